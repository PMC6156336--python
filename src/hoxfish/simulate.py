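"""Synthetic embryo fields with known ground truth.

The simulator emulates what triple-label DNA FISH / nascent-transcript RNA
FISH acquisition of a Drosophila embryo looks like to the analysis pipeline:

* a field of non-overlapping spherical nuclei partitioned into parasegments
  tiled along the anteroposterior axis;
* per nucleus, a triplet of locus positions (A, B, C) whose pairwise
  distances follow configurable compact/open distributions — locus A is
  placed uniformly inside the nucleus and B, C on uniformly random 3D
  directions at drawn radii, the simplest isotropic model consistent with
  distance-only statistics;
* per parasegment and gene, a configurable fraction of transcribing nuclei
  (a nascent-transcript spot at the nucleus);
* rigid per-channel chromatic shifts, anisotropic Gaussian PSF blur, and
  Poisson + Gaussian read noise.

Every run is deterministic for a fixed :class:`~hoxfish.config.SimConfig`
(including its seed), and the returned ground-truth table carries the true
positions, distances, expression flags and applied shifts so each pipeline
stage can be checked against a known answer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .config import FISH_CHANNELS, ConfigError, SimConfig
from .stack_io import ImageStack, ParasegmentROI

_MAX_PLACEMENT_ATTEMPTS = 5000


class PlacementError(RuntimeError):
    """Raised when a nucleus or locus cannot be placed inside the field."""


# ---------------------------------------------------------------------------
# geometry helpers


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_nuclei(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pack non-overlapping spherical nuclei into each PS polygon (xy) by
    rejection sampling; z is confined so the sphere stays inside the stack."""
    nx, ny, nz = config.field_size
    vs_xy, vs_z = config.voxel_size_xy, config.voxel_size_z
    r = config.nucleus_radius
    z_extent = (nz - 1) * vs_z
    z_lo, z_hi = min(r, z_extent / 2), max(z_extent - r, z_extent / 2)
    rows = []
    centers: list[np.ndarray] = []
    nucleus_id = 0
    for label, poly in config.parasegments:
        shape = Polygon(np.asarray(poly, dtype=float))
        minx, miny, maxx, maxy = shape.bounds
        for _ in range(config.nuclei_per_ps):
            for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                x_px = rng.uniform(minx, maxx)
                y_px = rng.uniform(miny, maxy)
                if not shape.contains(Point(x_px, y_px)):
                    continue
                center = np.array([x_px * vs_xy, y_px * vs_xy, rng.uniform(z_lo, z_hi)])
                if all(np.linalg.norm(center - c) >= 2 * r * 0.9 for c in centers):
                    break
            else:
                raise PlacementError(
                    f"could not place nucleus {nucleus_id} in {label!r} after "
                    f"{_MAX_PLACEMENT_ATTEMPTS} attempts (field too crowded)")
            centers.append(center)
            rows.append({"nucleus_id": nucleus_id, "ps_label": label,
                         "nucleus_x_nm": center[0], "nucleus_y_nm": center[1],
                         "nucleus_z_nm": center[2]})
            nucleus_id += 1
    return pd.DataFrame(rows)


def _place_loci(config: SimConfig, nuclei: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Draw locus triplets per nucleus: A uniform in the nucleus, B and C at
    radii drawn from the per-PS distance models on random directions."""
    out = nuclei.copy()
    r = config.nucleus_radius
    pos = {locus: np.empty((len(nuclei), 3)) for locus in "abc"}
    for i, row in enumerate(nuclei.itertuples(index=False)):
        center = np.array([row.nucleus_x_nm, row.nucleus_y_nm, row.nucleus_z_nm])
        d_ab = config.distance_model_for(row.ps_label, "ab").draw(rng, 1)[0]
        d_ac = config.distance_model_for(row.ps_label, "ac").draw(rng, 1)[0]
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            # uniform point in the inner half-radius ball keeps partners inside
            a = center + rng.uniform(-1, 1, 3) * r / 2
            if np.linalg.norm(a - center) > r / 2:
                continue
            b = a + d_ab * _random_unit_vectors(rng, 1)[0]
            c = a + d_ac * _random_unit_vectors(rng, 1)[0]
            if _inside_field(config, a) and _inside_field(config, b) and _inside_field(config, c):
                break
        else:
            raise PlacementError(
                f"could not place locus triplet for nucleus {row.nucleus_id}")
        pos["a"][i], pos["b"][i], pos["c"][i] = a, b, c
    for locus in "abc":
        for j, axis in enumerate("xyz"):
            out[f"{locus}_{axis}_nm"] = pos[locus][:, j]
    out["d_ab_nm"] = np.linalg.norm(pos["a"] - pos["b"], axis=1)
    out["d_bc_nm"] = np.linalg.norm(pos["b"] - pos["c"], axis=1)
    out["d_ac_nm"] = np.linalg.norm(pos["a"] - pos["c"], axis=1)
    return out


def _inside_field(config: SimConfig, p: np.ndarray, margin_px: float = 1.0) -> bool:
    nx, ny, nz = config.field_size
    lim = np.array([(nx - 1 - margin_px) * config.voxel_size_xy,
                    (ny - 1 - margin_px) * config.voxel_size_xy,
                    (nz - 1) * config.voxel_size_z])
    lo = np.array([margin_px * config.voxel_size_xy,
                   margin_px * config.voxel_size_xy, 0.0])
    return bool(np.all(p >= lo) and np.all(p <= lim))


# ---------------------------------------------------------------------------
# rendering


def render_spots(shape_zyx: tuple[int, int, int], centers_nm: np.ndarray,
                 voxel_size_xy: float, voxel_size_z: float,
                 sigma_xy_nm: float, sigma_z_nm: float,
                 amplitude: float = 100.0) -> np.ndarray:
    """Render point emitters as anisotropic 3D Gaussians on the voxel grid.

    ``centers_nm`` is (n, 3) in (x, y, z) nm. Each Gaussian is added on a
    local window of ±4σ, which keeps rendering O(n) in the number of spots.
    """
    img = np.zeros(shape_zyx, dtype=np.float64)
    if len(centers_nm) == 0:
        return img
    nz, ny, nx = shape_zyx
    sx = sigma_xy_nm / voxel_size_xy
    sz = sigma_z_nm / voxel_size_z
    half_xy = int(np.ceil(4 * sx)) + 1
    half_z = int(np.ceil(4 * sz)) + 1
    for cx_nm, cy_nm, cz_nm in np.asarray(centers_nm, dtype=float):
        cx, cy, cz = cx_nm / voxel_size_xy, cy_nm / voxel_size_xy, cz_nm / voxel_size_z
        x0, x1 = max(0, int(cx) - half_xy), min(nx, int(cx) + half_xy + 1)
        y0, y1 = max(0, int(cy) - half_xy), min(ny, int(cy) + half_xy + 1)
        z0, z1 = max(0, int(cz) - half_z), min(nz, int(cz) + half_z + 1)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                                 np.arange(x0, x1), indexing="ij")
        g = amplitude * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sx ** 2)
                                 + (zz - cz) ** 2 / (2 * sz ** 2)))
        img[z0:z1, y0:y1, x0:x1] += g
    return img


def _render_nuclei(config: SimConfig, nuclei: pd.DataFrame) -> np.ndarray:
    """DAPI channel: hard spheres at nucleus centres (unit intensity inside)."""
    nz, ny, nx = config.field_size[2], config.field_size[1], config.field_size[0]
    img = np.zeros((nz, ny, nx), dtype=np.float64)
    vs_xy, vs_z = config.voxel_size_xy, config.voxel_size_z
    r = config.nucleus_radius
    rx, rz = int(np.ceil(r / vs_xy)) + 1, int(np.ceil(r / vs_z)) + 1
    for row in nuclei.itertuples(index=False):
        cx, cy, cz = (row.nucleus_x_nm / vs_xy, row.nucleus_y_nm / vs_xy,
                      row.nucleus_z_nm / vs_z)
        x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 1)
        y0, y1 = max(0, int(cy) - rx), min(ny, int(cy) + rx + 1)
        z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 1)
        zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                                 np.arange(x0, x1), indexing="ij")
        dist2 = (((xx - cx) * vs_xy) ** 2 + ((yy - cy) * vs_xy) ** 2
                 + ((zz - cz) * vs_z) ** 2)
        img[z0:z1, y0:y1, x0:x1] += (dist2 <= r ** 2) * config.spot_amplitude
    return img


# ---------------------------------------------------------------------------
# public API


def simulate_embryo(config: SimConfig):
    """Simulate one embryo field.

    Returns
    -------
    stacks : list of ImageStack
        One per channel: "dapi", the three FISH channels (A488/A555/A647 for
        loci A/B/C, each displaced by its chromatic shift), and one
        ``rna_<gene>`` channel per configured gene.
    truth : pandas.DataFrame
        Per-nucleus ground truth: PS label, nucleus centre, true locus
        positions and pairwise distances (nm), expression flags, applied
        per-channel shifts.
    rois : list of ParasegmentROI
        The parasegment polygons in pixel coordinates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xE0B]))
    nuclei = _place_nuclei(config, rng)
    truth = _place_loci(config, nuclei, rng)
    truth.insert(0, "embryo_id", config.embryo_id)
    truth["stage_class"] = config.stage_class

    # expression flags
    for gene in config.genes:
        flags = np.zeros(len(truth), dtype=bool)
        for ps in config.ps_labels:
            mask = (truth["ps_label"] == ps).to_numpy()
            frac = config.expression_fraction_for(ps, gene)
            flags[mask] = rng.random(int(mask.sum())) < frac
        truth[f"expr_{gene}"] = flags

    # record applied shifts (global rigid translation per channel)
    for ch in FISH_CHANNELS:
        shift = config.shift_for(ch)
        for j, axis in enumerate("xyz"):
            truth[f"shift_{ch}_{axis}_nm"] = shift[j]

    shape = (config.field_size[2], config.field_size[1], config.field_size[0])
    stacks = [ImageStack(_apply_noise(_render_nuclei(config, nuclei), config, rng),
                         config.voxel_size_xy, config.voxel_size_z, "dapi")]
    for locus, ch in zip("abc", FISH_CHANNELS):
        centers = truth[[f"{locus}_x_nm", f"{locus}_y_nm", f"{locus}_z_nm"]].to_numpy()
        centers = centers + config.shift_for(ch)[None, :]
        img = render_spots(shape, centers, config.voxel_size_xy, config.voxel_size_z,
                           config.psf_sigma_xy, config.psf_sigma_z,
                           config.spot_amplitude)
        stacks.append(ImageStack(_apply_noise(img, config, rng),
                                 config.voxel_size_xy, config.voxel_size_z, ch))
    for gene in config.genes:
        expressing = truth[truth[f"expr_{gene}"]]
        centers = expressing[["nucleus_x_nm", "nucleus_y_nm", "nucleus_z_nm"]].to_numpy()
        img = render_spots(shape, centers, config.voxel_size_xy, config.voxel_size_z,
                           config.psf_sigma_xy, config.psf_sigma_z,
                           config.spot_amplitude)
        stacks.append(ImageStack(_apply_noise(img, config, rng),
                                 config.voxel_size_xy, config.voxel_size_z,
                                 f"rna_{gene}"))

    rois = [ParasegmentROI(label=label, polygon=poly, voxel_size_xy=config.voxel_size_xy)
            for label, poly in config.parasegments]
    return stacks, truth, rois


def _apply_noise(img: np.ndarray, config: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    return img if config.noise.is_clean else config.noise.apply(img, rng)


def simulate_distance_table(config: SimConfig, n_embryos: int = 1) -> pd.DataFrame:
    """Fast path: draw pairwise distances directly from the distance models,
    bypassing locus placement and imaging.

    One row per (embryo, parasegment, nucleus, pair) with columns
    ``embryo_id, ps_label, pair, distance_nm``. Pairs "ab" and "ac" are the
    modelled radii; "bc" is drawn from its own model when one is configured,
    otherwise derived from the isotropic placement geometry (two random
    directions from a shared vertex), matching :func:`simulate_embryo`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xD15]))
    rows = []
    for e in range(n_embryos):
        embryo = config.embryo_id if n_embryos == 1 else f"{config.embryo_id}_{e}"
        for ps in config.ps_labels:
            n = config.nuclei_per_ps
            d_ab = config.distance_model_for(ps, "ab").draw(rng, n)
            d_ac = config.distance_model_for(ps, "ac").draw(rng, n)
            if (ps, "bc") in config.distance_model or "bc" in config.distance_model:
                d_bc = config.distance_model_for(ps, "bc").draw(rng, n)
            else:
                # angle between the two random directions: cos uniform on [-1, 1]
                cos_theta = rng.uniform(-1.0, 1.0, n)
                d_bc = np.sqrt(d_ab ** 2 + d_ac ** 2 - 2 * d_ab * d_ac * cos_theta)
            for pair, dist in (("ab", d_ab), ("bc", d_bc), ("ac", d_ac)):
                for k in range(n):
                    rows.append({"embryo_id": embryo, "ps_label": ps, "pair": pair,
                                 "nucleus": k, "distance_nm": dist[k]})
    return pd.DataFrame(rows)
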