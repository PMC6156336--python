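"""Nascent-transcript quantification: per-parasegment spot densities,
min–max relative densities, and ectopic-expression / downregulation calls.

The unit of replication is the embryo: spot counts are turned into one
density per (gene, embryo, parasegment), and mutant-vs-control comparisons
are two-tailed Mann–Whitney tests on per-embryo densities at P < 0.01, with
no multiple-testing correction by default (a Benjamini–Hochberg option is
available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locus_stats import compare_pooled
from .stack_io import ParasegmentROI

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDensity:
    """Spot density of one gene in one parasegment of one embryo."""

    gene: str
    embryo_id: str
    ps_label: str
    spot_count: int
    ps_area_um2: float
    density: float  # spots / µm²
    relative_density: float | None = None  # min-max normalized within a series


@dataclass
class DerepressionCall:
    """Outcome of a mutant-vs-control expression comparison in one cell
    (gene × parasegment group × stage class)."""

    gene: str
    ps_label: str
    stage_class: str
    direction: str  # "ectopic_up" | "down" | "none"
    p_value: float


def density_per_ps(counts: pd.DataFrame,
                   rois: list[ParasegmentROI]) -> list[ExpressionDensity]:
    """Compute spot densities: spot count divided by parasegment area (µm²).

    ``counts`` needs columns gene, embryo_id, ps_label, spot_count; every
    ps_label must have a matching ROI. Grouped parasegments (labels like
    "PS2-PS4" mapping to several ROIs) are handled by
    :func:`grouped_density`.
    """
    areas = {roi.label: roi.area_um2 for roi in rois}
    out = []
    for row in counts.itertuples(index=False):
        if row.ps_label not in areas:
            raise KeyError(f"no ROI for parasegment {row.ps_label!r}")
        area = areas[row.ps_label]
        out.append(ExpressionDensity(
            gene=str(row.gene), embryo_id=str(row.embryo_id),
            ps_label=str(row.ps_label), spot_count=int(row.spot_count),
            ps_area_um2=area, density=float(row.spot_count) / area))
    return out


def grouped_density(counts: pd.DataFrame, rois: list[ParasegmentROI],
                    groups: dict[str, list[str]]) -> list[ExpressionDensity]:
    """Density for merged parasegment ranges (e.g. "PS2-PS4"): counts and
    areas are summed over member parasegments before dividing."""
    areas = {roi.label: roi.area_um2 for roi in rois}
    out = []
    for group_label, members in groups.items():
        missing = [m for m in members if m not in areas]
        if missing:
            raise KeyError(f"no ROI for parasegment(s) {missing}")
        area = sum(areas[m] for m in members)
        sub = counts[counts["ps_label"].isin(members)]
        for (gene, embryo), block in sub.groupby(["gene", "embryo_id"], sort=True):
            out.append(ExpressionDensity(
                gene=str(gene), embryo_id=str(embryo), ps_label=group_label,
                spot_count=int(block["spot_count"].sum()), ps_area_um2=area,
                density=float(block["spot_count"].sum()) / area))
    return out


def relative_density(densities) -> np.ndarray:
    """Min–max normalize a density series to [0, 1].

    A constant series maps to all zeros (documented degenerate rule). The
    result is invariant under positive affine transforms of the input.
    """
    x = np.asarray(densities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def call_derepression(mutant: list[ExpressionDensity],
                      control: list[ExpressionDensity],
                      stage_class: str = "",
                      alpha: float = 0.01,
                      bh_correct: bool = False) -> list[DerepressionCall]:
    """Flag ectopic expression or downregulation per (gene, parasegment).

    Per cell, a two-tailed Mann–Whitney U-test compares per-embryo densities;
    the call is "ectopic_up" when the mutant median exceeds the control
    median at p < alpha, "down" when it is lower at p < alpha, else "none".
    Cells with fewer than two embryos on either side are skipped. With
    ``bh_correct`` the p-values are Benjamini–Hochberg adjusted across cells
    before calling (off by default).
    """
    def by_cell(densities):
        table: dict[tuple[str, str], list[float]] = {}
        for d in densities:
            table.setdefault((d.gene, d.ps_label), []).append(d.density)
        return table

    mut, ctl = by_cell(mutant), by_cell(control)
    cells = sorted(set(mut) & set(ctl))
    raw: list[tuple[tuple[str, str], float, float, float]] = []
    for cell in cells:
        a, b = mut[cell], ctl[cell]
        if len(a) < 2 or len(b) < 2:
            logger.info("skipping %s: fewer than 2 embryos per genotype", cell)
            continue
        res = compare_pooled(a, b)
        raw.append((cell, res.p_value, float(np.median(a)), float(np.median(b))))

    if bh_correct and raw:
        order = np.argsort([r[1] for r in raw])
        m = len(raw)
        adj = np.empty(m)
        running = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = m - rank  # 1-based rank from largest p
            running = min(running, raw[idx][1] * m / i)
            adj[idx] = running
        raw = [(c, adj[i], ma, mb) for i, (c, p, ma, mb) in enumerate(raw)]

    calls = []
    for (gene, ps), p, med_mut, med_ctl in raw:
        if p < alpha and med_mut > med_ctl:
            direction = "ectopic_up"
        elif p < alpha and med_mut < med_ctl:
            direction = "down"
        else:
            direction = "none"
        calls.append(DerepressionCall(gene=gene, ps_label=ps,
                                      stage_class=stage_class,
                                      direction=direction, p_value=float(p)))
    return calls


def densities_to_frame(densities: list[ExpressionDensity]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": d.gene, "embryo_id": d.embryo_id, "ps_label": d.ps_label,
        "spot_count": d.spot_count, "ps_area_um2": d.ps_area_um2,
        "density_per_um2": d.density,
        "relative_density": d.relative_density,
    } for d in densities])
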