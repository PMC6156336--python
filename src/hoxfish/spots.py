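"""FISH spot detection and localization.

Two detection paths mirror how the two kinds of signal are used:

* RNA FISH (expression): Gaussian filter → maximum-intensity z-projection →
  2D local maxima counting inside parasegment ROIs. Only counts matter.
* DNA FISH (distances): 3×3×3 smoothing filter → global threshold →
  3D connected components → intensity-weighted centre-of-mass centroids in
  physical (nm) coordinates. Sub-voxel centroids matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .stack_io import ImageStack, ParasegmentROI

logger = logging.getLogger(__name__)


@dataclass
class Spot:
    """A detected FISH/protein signal.

    ``centroid`` is the (x, y, z) position in nm; ``voxel_count`` the size of
    the segmented component; ``ps_label`` the parasegment assignment (None
    when outside every ROI).
    """

    channel_label: str
    centroid: tuple[float, float, float]
    peak_intensity: float
    voxel_count: int
    ps_label: str | None = None

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass
class DetectionParams:
    """Tunable detection parameters.

    gaussian_radius_px
        σ (pixels) of the RNA-path Gaussian filter; default 1 px, the common
        reading of "Gaussian filter with a radius of 1".
    fine_filter_px
        Edge of the DNA-path cubic smoothing filter (default 3, i.e. 3×3×3).
    fine_filter_kind
        "mean" (default, minimal smoothing) or "median".
    maxima_prominence
        Absolute height a 2D maximum must exceed to be counted. None derives
        a scale-free default of 5× the projected image's median absolute
        deviation above its median.
    threshold_method / fixed_threshold
        DNA segmentation threshold: "otsu" (parameter-free default) or
        "fixed" with an explicit value.
    min_voxels
        Minimum component size kept (default 4 rejects single-voxel noise).
    """

    gaussian_radius_px: float = 1.0
    fine_filter_px: int = 3
    fine_filter_kind: str = "mean"
    maxima_prominence: float | None = None
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_voxels: int = 4

    def __post_init__(self) -> None:
        if self.gaussian_radius_px <= 0 or self.fine_filter_px <= 0:
            raise ValueError("filter radii must be positive")
        if self.fine_filter_kind not in ("mean", "median"):
            raise ValueError("fine_filter_kind must be 'mean' or 'median'")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if (self.threshold_method == "fixed") != (self.fixed_threshold is not None):
            raise ValueError("fixed_threshold is required iff threshold_method='fixed'")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


def _default_prominence(proj: np.ndarray) -> float:
    med = np.median(proj)
    mad = np.median(np.abs(proj - med))
    return float(med + 5.0 * max(mad, 1e-12))


def count_rna_spots(stack: ImageStack, rois: list[ParasegmentROI],
                    params: DetectionParams | None = None) -> pd.DataFrame:
    """Count nascent-transcript spots per parasegment.

    Pipeline: per-slice Gaussian filter → max-intensity z-projection →
    2D local maxima above ``maxima_prominence`` → point-in-polygon ROI
    assignment (first ROI in file order wins on boundaries). Maxima outside
    every ROI are discarded. Returns a table (ps_label, spot_count).
    """
    if not rois:
        raise ValueError("count_rna_spots needs at least one ROI")
    params = params or DetectionParams()
    smoothed = ndimage.gaussian_filter(
        stack.voxels.astype(np.float64),
        sigma=(0, params.gaussian_radius_px, params.gaussian_radius_px))
    proj = smoothed.max(axis=0)
    counts = {roi.label: 0 for roi in rois}
    if proj.max() > proj.min():
        prom = (params.maxima_prominence if params.maxima_prominence is not None
                else _default_prominence(proj))
        peaks = peak_local_max(proj, min_distance=2, threshold_abs=prom,
                               exclude_border=False)
        for row, col in peaks:  # (y, x) pixel indices
            for roi in rois:
                if roi.contains_px(col, row):
                    counts[roi.label] += 1
                    break
    return pd.DataFrame({"ps_label": list(counts), "spot_count": list(counts.values())})


def segment_dna_spots(stack: ImageStack,
                      params: DetectionParams | None = None) -> list[Spot]:
    """Segment DNA FISH spots in 3D and localize their centroids.

    Pipeline: 3×3×3 smoothing filter → global threshold (Otsu by default) →
    26-connected components → drop components below ``min_voxels`` →
    intensity-weighted centre of mass, converted to nm with the stack's
    anisotropic voxel sizes.
    """
    params = params or DetectionParams()
    img = stack.voxels.astype(np.float64)
    size = params.fine_filter_px
    if params.fine_filter_kind == "mean":
        smoothed = ndimage.uniform_filter(img, size=size)
    else:
        smoothed = ndimage.median_filter(img, size=size)
    if smoothed.max() <= smoothed.min():
        return []  # flat image: nothing to segment
    if params.threshold_method == "otsu":
        thresh = float(threshold_otsu(smoothed))
    else:
        thresh = float(params.fixed_threshold)
        if thresh > smoothed.max():
            logger.warning("fixed threshold %.3g above image maximum %.3g: no objects",
                           thresh, smoothed.max())
            return []
    mask = smoothed > thresh
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return []
    spots: list[Spot] = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        count = int(sub.sum())
        if count < params.min_voxels:
            continue
        weights = smoothed[sl] * sub
        zc, yc, xc = ndimage.center_of_mass(weights)
        zc += sl[0].start
        yc += sl[1].start
        xc += sl[2].start
        peak = float((img[sl] * sub).max())
        spots.append(Spot(
            channel_label=stack.channel_label,
            centroid=(xc * stack.voxel_size_xy, yc * stack.voxel_size_xy,
                      zc * stack.voxel_size_z),
            peak_intensity=peak,
            voxel_count=count))
    return spots


def assign_spots_to_rois(spots: list[Spot],
                         rois: list[ParasegmentROI]) -> list[Spot]:
    """Label each spot with the parasegment whose polygon contains its (x, y).

    Containment is 2D point-in-polygon on pixel coordinates; a spot on a
    shared boundary goes to the first ROI in file order (documented
    tie-break). Spots outside every ROI get ``ps_label=None``.
    """
    for spot in spots:
        spot.ps_label = None
        for roi in rois:
            if roi.contains_nm(spot.centroid[0], spot.centroid[1]):
                spot.ps_label = roi.label
                break
    return spots


def spots_to_frame(spots: list[Spot]) -> pd.DataFrame:
    """Long-format spot table (one row per spot) for CSV output."""
    return pd.DataFrame([{
        "channel": s.channel_label,
        "x_nm": s.centroid[0], "y_nm": s.centroid[1], "z_nm": s.centroid[2],
        "peak": s.peak_intensity, "voxels": s.voxel_count,
        "ps_label": s.ps_label if s.ps_label is not None else "",
    } for s in spots])


def frame_to_spots(frame: pd.DataFrame) -> list[Spot]:
    return [Spot(channel_label=str(r.channel),
                 centroid=(float(r.x_nm), float(r.y_nm), float(r.z_nm)),
                 peak_intensity=float(r.peak), voxel_count=int(r.voxels),
                 ps_label=(str(r.ps_label) if isinstance(r.ps_label, str)
                           and r.ps_label else None))
            for r in frame.itertuples(index=False)]
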