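"""Image stacks, parasegment ROIs and sample metadata: containers and file I/O.

Conventions used throughout the package:

* voxel arrays are ordered ``(z, y, x)``;
* physical coordinates are reported in nanometres, ordered ``(x, y, z)``;
* pixel coordinates are 0-based voxel-centre coordinates;
* result tables are UTF-8 CSV with a header row and ``.`` decimal separator.

Voxel sizes are supplied by the caller (config/CLI), never parsed from TIFF
tags, which keeps calibration independent of writer dialects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

#: closed vocabulary of genotypes (wild type, the two cPRC1 null mutants and
#: their sibling controls)
GENOTYPES = ("WT", "ph_del", "Pc_XT109", "ph_control", "Pc_control")

#: the four ordinal developmental-stage classes (hours after fertilization)
STAGE_CLASSES = ("3:50-4:50", "4:50-6:00", "6:00-7:20", "7:20-12:00")


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass
class ImageStack:
    """One channel's 3D voxel grid with its physical calibration.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative finite intensities.
    voxel_size_xy, voxel_size_z : float
        Lateral / axial voxel size in nm. Acquisition is anisotropic
        (e.g. 73 nm xy, 300 nm z for DNA FISH), so the two are kept separate.
    channel_label : str
        Free-form channel name (e.g. "A555", "dapi", "rna_Ubx").
    """

    voxels: np.ndarray
    voxel_size_xy: float
    voxel_size_z: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"stack must be 3D (z, y, x); got shape {self.voxels.shape}")
        if not (self.voxel_size_xy > 0 and self.voxel_size_z > 0):
            raise ValueError("voxel sizes must be > 0")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def bounds_nm(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in nm spanned by voxel centres."""
        nz, ny, nx = self.voxels.shape
        return ((nx - 1) * self.voxel_size_xy,
                (ny - 1) * self.voxel_size_xy,
                (nz - 1) * self.voxel_size_z)


@dataclass
class ParasegmentROI:
    """A labelled 2D polygon along the A/P axis used to bin nuclei and spots.

    ``polygon`` vertices are xy pixel coordinates; ``area_um2`` is the
    shoelace area scaled by the squared pixel size.
    """

    label: str
    polygon: np.ndarray  # (n, 2) array of (x, y) pixel vertices
    voxel_size_xy: float  # nm per pixel
    _shape: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise FormatError(f"ROI {self.label!r}: polygon needs >= 3 (x, y) vertices")
        shape = Polygon(self.polygon)
        if not shape.is_valid or shape.area <= 0:
            raise FormatError(f"ROI {self.label!r}: polygon is self-intersecting or degenerate")
        self._shape = shape

    @property
    def area_um2(self) -> float:
        """Polygon area in µm² (pixel area × (pixel size in µm)²)."""
        return self._shape.area * (self.voxel_size_xy / 1000.0) ** 2

    def contains_px(self, x: float, y: float) -> bool:
        """Point-in-polygon on pixel coordinates; boundary counts as inside."""
        return bool(self._shape.covers(Point(x, y)))

    def contains_nm(self, x_nm: float, y_nm: float) -> bool:
        return self.contains_px(x_nm / self.voxel_size_xy, y_nm / self.voxel_size_xy)


@dataclass
class SampleMeta:
    """Per-embryo metadata: genotype and developmental-stage class."""

    embryo_id: str
    genotype: str
    stage_class: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.stage_class not in STAGE_CLASSES:
            raise ValueError(
                f"unknown stage class {self.stage_class!r}; expected one of {STAGE_CLASSES}")


# ---------------------------------------------------------------------------
# TIFF stacks


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page grayscale TIFF, one page per z-slice."""
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")


def read_stack(path, voxel_size_xy: float, voxel_size_z: float,
               channel_label: str = "") -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    All pages must share a shape; the physical calibration is taken from the
    arguments, not from TIFF tags.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, tifffile.TiffFileError) as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path}: TIFF contains no pages")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.shape != shape0:
            raise FormatError(f"{path}: page {i} has shape {page.shape}, expected {shape0}")
    voxels = np.stack(pages, axis=0)
    if voxels.ndim == 2:  # single page
        voxels = voxels[None]
    return ImageStack(voxels=voxels, voxel_size_xy=voxel_size_xy,
                      voxel_size_z=voxel_size_z, channel_label=channel_label)


# ---------------------------------------------------------------------------
# ROI JSON
#
# Schema: {"voxel_size_xy_nm": float,
#          "rois": [{"label": str, "polygon": [[x, y], ...]}, ...]}


def write_rois(path, rois: list[ParasegmentROI]) -> None:
    if not rois:
        raise ValueError("no ROIs to write")
    payload = {
        "voxel_size_xy_nm": rois[0].voxel_size_xy,
        "rois": [{"label": r.label, "polygon": np.asarray(r.polygon).tolist()} for r in rois],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_rois(path, voxel_size_xy: float | None = None) -> list[ParasegmentROI]:
    """Read labelled ROI polygons from JSON and validate them.

    A duplicated label or a self-intersecting polygon raises
    :class:`FormatError` naming the offending label. ``voxel_size_xy``
    overrides the pixel size recorded in the file.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    vs = voxel_size_xy if voxel_size_xy is not None else payload.get("voxel_size_xy_nm")
    if vs is None or vs <= 0:
        raise FormatError(f"{path}: missing or invalid voxel_size_xy_nm")
    rois: list[ParasegmentROI] = []
    seen: set[str] = set()
    for entry in payload["rois"]:
        label = entry["label"]
        if label in seen:
            raise FormatError(f"{path}: duplicate ROI label {label!r}")
        seen.add(label)
        rois.append(ParasegmentROI(label=label, polygon=entry["polygon"], voxel_size_xy=vs))
    return rois


# ---------------------------------------------------------------------------
# CSV result tables


def write_table(path, frame, config_hash: str | None = None) -> None:
    """Write a result table as CSV, optionally with a provenance comment line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


def read_table(path):
    import pandas as pd

    return pd.read_csv(path, comment="#")
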