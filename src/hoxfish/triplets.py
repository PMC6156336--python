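"""Triplet matching, pairwise 3D distances and chromatic-aberration calibration.

Spots from the three FISH channels are matched into (A, B, C) trios: for
each anchor spot (middle locus, channel A555, by default) the nearest spot
in each partner channel is found, and the trio is kept only when both
anchor-to-partner distances are at or below 1.5 µm. Distance distributions
downstream therefore have support [0, 1.5 µm] by construction.

Chromatic aberration is calibrated from a same-locus triple-label control
(three dyes hybridized to a single locus): the median apparent distance per
channel pair is the offset, subtracted from summary medians (floored at 0).
Raw distributions are always reported uncorrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .spots import Spot

logger = logging.getLogger(__name__)

#: acceptance radius for the two anchor-to-partner distances (nm)
DEFAULT_RADIUS_NM = 1500.0


@dataclass
class Triplet:
    """A matched (A, B, C) spot trio with its three pairwise distances (nm)."""

    spot_a: Spot
    spot_b: Spot
    spot_c: Spot
    d_ab: float
    d_bc: float
    d_ac: float
    ps_label: str | None = None
    embryo_id: str = ""


@dataclass
class ChromaticCalibration:
    """Median apparent inter-channel distances for a single physical locus (nm)."""

    offset_ab: float
    offset_bc: float
    offset_ac: float

    def __post_init__(self) -> None:
        if min(self.offset_ab, self.offset_bc, self.offset_ac) < 0:
            raise ValueError("chromatic offsets must be >= 0")

    def offset(self, pair: str) -> float:
        return {"ab": self.offset_ab, "bc": self.offset_bc, "ac": self.offset_ac}[pair]


def pairwise_distance(p, q) -> float:
    """Euclidean distance between two (x, y, z) points in nm."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def match_triplets(spots_a: list[Spot], spots_b: list[Spot], spots_c: list[Spot],
                   radius_nm: float = DEFAULT_RADIUS_NM,
                   anchor: str = "b", embryo_id: str = "") -> list[Triplet]:
    """Match three channels' spots into accepted triplets.

    For each anchor spot the nearest spot of each partner channel is found;
    the candidate is accepted iff both anchor-to-partner distances are
    ≤ ``radius_nm``. Partner spots are used at most once: candidates are
    processed greedily in ascending order of their larger anchor-partner
    distance (ties broken by anchor order), and a candidate whose partner is
    already taken is dropped.

    The triplet's ``ps_label`` and ``embryo_id`` come from the anchor spot /
    argument. Only ``anchor="b"`` (the middle locus, A555) is currently
    wired; the channel roles can be permuted by the caller.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")
    if anchor != "b":
        raise ValueError("anchor must be 'b'; permute channel arguments instead")
    if not spots_a or not spots_b or not spots_c:
        return []

    xyz_a = np.array([s.xyz for s in spots_a])
    xyz_c = np.array([s.xyz for s in spots_c])
    tree_a = cKDTree(xyz_a)
    tree_c = cKDTree(xyz_c)

    candidates = []  # (sort_key, anchor_idx, a_idx, c_idx, d_ab, d_bc)
    for bi, sb in enumerate(spots_b):
        d_ab, ai = tree_a.query(sb.xyz)
        d_cb, ci = tree_c.query(sb.xyz)
        if d_ab <= radius_nm and d_cb <= radius_nm:
            candidates.append((max(d_ab, d_cb), bi, int(ai), int(ci),
                               float(d_ab), float(d_cb)))
    candidates.sort(key=lambda t: (t[0], t[1]))

    used_a: set[int] = set()
    used_c: set[int] = set()
    triplets: list[Triplet] = []
    for _, bi, ai, ci, d_ab, d_bc in candidates:
        if ai in used_a or ci in used_c:
            continue
        used_a.add(ai)
        used_c.add(ci)
        sa, sb, sc = spots_a[ai], spots_b[bi], spots_c[ci]
        triplets.append(Triplet(
            spot_a=sa, spot_b=sb, spot_c=sc,
            d_ab=d_ab, d_bc=d_bc,
            d_ac=pairwise_distance(sa.xyz, sc.xyz),
            ps_label=sb.ps_label, embryo_id=embryo_id))
    return triplets


def calibrate_chromatic(triplets_single_locus: list[Triplet],
                        min_triplets: int = 10) -> ChromaticCalibration:
    """Estimate per-pair chromatic offsets from a same-locus control.

    The three dyes label one physical locus, so any apparent pairwise
    distance is chromatic displacement plus localization error; the per-pair
    median is the calibration offset.
    """
    if len(triplets_single_locus) < min_triplets:
        raise ValueError(
            f"need at least {min_triplets} control triplets, got {len(triplets_single_locus)}")
    return ChromaticCalibration(
        offset_ab=float(np.median([t.d_ab for t in triplets_single_locus])),
        offset_bc=float(np.median([t.d_bc for t in triplets_single_locus])),
        offset_ac=float(np.median([t.d_ac for t in triplets_single_locus])))


def correct_median_distances(medians: dict[str, float],
                             cal: ChromaticCalibration) -> dict[str, float]:
    """Subtract the per-pair chromatic offset from summary medians, floored at 0.

    Applied to medians only — raw distance distributions stay uncorrected.
    """
    out = {}
    for pair, median in medians.items():
        if median < 0:
            raise ValueError(f"median for pair {pair!r} is negative")
        out[pair] = max(0.0, float(median) - cal.offset(pair))
    return out


def triplets_to_frame(triplets: list[Triplet]):
    """Long-format distance table: one row per (triplet, pair)."""
    import pandas as pd

    rows = []
    for i, t in enumerate(triplets):
        for pair, d in (("ab", t.d_ab), ("bc", t.d_bc), ("ac", t.d_ac)):
            rows.append({"embryo_id": t.embryo_id, "triplet": i,
                         "ps_label": t.ps_label if t.ps_label is not None else "",
                         "pair": pair, "distance_nm": d})
    return pd.DataFrame(rows)
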