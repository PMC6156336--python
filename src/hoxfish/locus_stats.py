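"""Distance-side statistics.

Distance measurements are summarized in the two complementary presentations
used throughout the analysis:

* *pooled*: distances from all embryos of one condition (same genotype,
  stage class and parasegment group) pooled into one distribution — the
  input to box plots and two-tailed Mann–Whitney U-tests;
* *per-embryo medians*: the median per parasegment of each embryo — the
  input to mean ± SEM curves and one-tailed Welch t-tests.

On top of these sit the difference-of-medians series (mutant − control per
stage class), proximity-to-foci percentages (< 400 nm by default), min–max
normalized expression/distance correlation, and differential-effect
scatterplots comparing the two mutants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .spots import Spot
from .stack_io import STAGE_CLASSES

logger = logging.getLogger(__name__)

#: p-value thresholds for significance stars
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: product n_a·n_b below which the Mann–Whitney null is enumerated exactly
EXACT_MWU_LIMIT = 400


@dataclass
class StatTestResult:
    test: str  # "mannwhitney_two_tailed" | "ttest_one_tailed"
    statistic: float
    p_value: float
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        self.stars = "ns"
        for threshold, label in STAR_THRESHOLDS:
            if self.p_value < threshold:
                self.stars = label
                break


@dataclass
class DistanceSummary:
    """Distance summary for one condition (genotype × stage × PS group × pair)."""

    genotype: str
    stage_class: str
    ps_label: str
    pair: str
    pooled: np.ndarray  # all distances, nm
    per_embryo_medians: np.ndarray  # one median per embryo, nm
    median: float
    quartiles: tuple[float, float]
    n_embryos: int
    sem: float | None  # None when n_embryos < 2 (SEM undefined)


@dataclass
class CorrelationMap:
    """Min–max normalized distance and expression series over a PS axis."""

    axis: list[str]
    dist_norm: np.ndarray
    exp_norm: np.ndarray
    r: float


def summarize_distances(distances: pd.DataFrame,
                        meta: pd.DataFrame | None = None,
                        grouping: tuple[str, ...] = ("genotype", "stage_class",
                                                     "ps_label", "pair"),
                        ) -> list[DistanceSummary]:
    """Summarize a long-format distance table per condition.

    ``distances`` needs columns embryo_id, ps_label, pair, distance_nm;
    ``meta`` (embryo_id, genotype, stage_class) is joined in when given,
    otherwise missing grouping columns default to "". Empty conditions are
    simply absent from the output.
    """
    frame = distances.copy()
    if meta is not None:
        frame = frame.merge(meta, on="embryo_id", how="left")
    for col in grouping:
        if col not in frame.columns:
            frame[col] = ""
    out = []
    for key, block in frame.groupby(list(grouping), sort=True):
        key = dict(zip(grouping, key if isinstance(key, tuple) else (key,)))
        pooled = block["distance_nm"].to_numpy(dtype=float)
        med_by_embryo = (block.groupby("embryo_id")["distance_nm"].median()
                         .to_numpy(dtype=float))
        n = len(med_by_embryo)
        sem = float(np.std(med_by_embryo, ddof=1) / math.sqrt(n)) if n >= 2 else None
        if sem is None:
            logger.info("condition %s has a single embryo: SEM undefined", key)
        q1, q3 = np.percentile(pooled, [25, 75])
        out.append(DistanceSummary(
            genotype=str(key.get("genotype", "")),
            stage_class=str(key.get("stage_class", "")),
            ps_label=str(key.get("ps_label", "")),
            pair=str(key.get("pair", "")),
            pooled=pooled, per_embryo_medians=med_by_embryo,
            median=float(np.median(pooled)), quartiles=(float(q1), float(q3)),
            n_embryos=n, sem=sem))
    return out


# ---------------------------------------------------------------------------
# hypothesis tests


def compare_pooled(a, b) -> StatTestResult:
    """Two-tailed Mann–Whitney U-test between two pooled distributions.

    The null distribution is enumerated exactly when n_a·n_b ≤ 400 and the
    samples are tie-free; otherwise the tie-corrected normal approximation
    (with continuity correction) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_pooled needs at least 2 values per side")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= EXACT_MWU_LIMIT and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatTestResult(test="mannwhitney_two_tailed",
                          statistic=float(res.statistic),
                          p_value=float(min(res.pvalue, 1.0)))


def compare_medians_ttest(a, b, alternative: str = "greater") -> StatTestResult:
    """One-tailed Welch t-test on per-embryo medians.

    ``alternative`` states the direction tested for sample ``a`` relative to
    ``b``. Two degenerate zero-variance samples with equal means yield
    p = 0.5 by convention (the one-tailed null centre).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_medians_ttest needs n >= 2 per side")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        logger.info("zero variance on both sides with equal means: p = 0.5")
        return StatTestResult(test="ttest_one_tailed", statistic=0.0, p_value=0.5)
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return StatTestResult(test="ttest_one_tailed",
                          statistic=float(res.statistic),
                          p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# derived series


def differential_effect(mutant: list[DistanceSummary],
                        control: list[DistanceSummary]) -> pd.DataFrame:
    """Difference of pooled medians (mutant − control) per matched condition.

    Conditions are matched on (pair, ps_label, stage_class); unmatched cells
    are omitted with a log entry. Rows are ordered along the four ordinal
    stage classes.
    """
    def index(summaries):
        return {(s.pair, s.ps_label, s.stage_class): s for s in summaries}

    mut, ctl = index(mutant), index(control)
    rows = []
    for key in mut:
        if key not in ctl:
            logger.info("no control condition for %s: omitted", (key,))
            continue
        pair, ps, stage = key
        rows.append({"pair": pair, "ps_label": ps, "stage_class": stage,
                     "delta_median_nm": mut[key].median - ctl[key].median})
    frame = pd.DataFrame(rows, columns=["pair", "ps_label", "stage_class",
                                        "delta_median_nm"])
    if len(frame):
        order = {s: i for i, s in enumerate(STAGE_CLASSES)}
        frame = frame.sort_values(
            ["pair", "ps_label", "stage_class"],
            key=lambda col: col.map(order) if col.name == "stage_class" else col,
        ).reset_index(drop=True)
    return frame


def proximity_fraction(gene_spots: list[Spot], foci: list[Spot],
                       cutoff_nm: float = 400.0) -> dict[str, float]:
    """Per-parasegment percentage of gene spots within ``cutoff_nm`` of the
    nearest protein focus, for one embryo.

    Returns {ps_label: percentage}. Raises ValueError when the embryo has no
    foci (the fraction is undefined; callers skip such embryos).
    """
    if not foci:
        raise ValueError("no foci in this embryo: proximity fraction undefined")
    tree = cKDTree(np.array([f.xyz for f in foci]))
    near: dict[str, list[bool]] = {}
    for spot in gene_spots:
        if spot.ps_label is None:
            continue
        d, _ = tree.query(spot.xyz)
        near.setdefault(spot.ps_label, []).append(bool(d < cutoff_nm))
    return {ps: 100.0 * np.mean(flags) for ps, flags in near.items()}


def mean_proximity_fraction(per_embryo: list[dict[str, float]]) -> dict[str, float]:
    """Average per-embryo proximity percentages across embryos, per PS."""
    table: dict[str, list[float]] = {}
    for fractions in per_embryo:
        for ps, value in fractions.items():
            table.setdefault(ps, []).append(value)
    return {ps: float(np.mean(v)) for ps, v in table.items()}


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    return np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)


def expression_distance_correlation(dist_series: pd.Series,
                                    exp_series: pd.Series) -> CorrelationMap:
    """Correlate chromatin opening with transcription along the PS axis.

    ``dist_series`` holds a locus-pair distance per parasegment and
    ``exp_series`` the summed relative expression density of the genes lying
    between the two loci (endpoint genes included). Both are min–max
    normalized and the Pearson r between them is reported. The two series
    must share the PS axis.
    """
    missing = [ps for ps in dist_series.index if ps not in exp_series.index]
    missing += [ps for ps in exp_series.index if ps not in dist_series.index]
    if missing:
        raise ValueError(f"PS axis mismatch; unmatched labels: {sorted(set(missing))}")
    axis = list(dist_series.index)
    dist_norm = _minmax(dist_series.to_numpy(dtype=float))
    exp_norm = _minmax(exp_series.reindex(axis).to_numpy(dtype=float))
    r = float(np.corrcoef(dist_norm, exp_norm)[0, 1])
    return CorrelationMap(axis=axis, dist_norm=dist_norm, exp_norm=exp_norm, r=r)


def differential_scatter(delta_dist: pd.Series,
                         delta_exp: pd.Series) -> tuple[pd.DataFrame, float | None]:
    """Scatter of differential mutant effects: x = Δdistance (between the two
    mutants, early stage), y = Δexpression (later stage), one point per
    parasegment shared by both series. Pearson r is reported when at least
    three parasegments are shared, else None.
    """
    shared = [ps for ps in delta_dist.index if ps in delta_exp.index]
    points = pd.DataFrame({
        "ps_label": shared,
        "delta_dist": delta_dist.loc[shared].to_numpy(dtype=float),
        "delta_exp": delta_exp.loc[shared].to_numpy(dtype=float),
    })
    if len(shared) < 3:
        logger.info("fewer than 3 shared parasegments: r not computed")
        return points, None
    r = float(np.corrcoef(points["delta_dist"], points["delta_exp"])[0, 1])
    return points, r


def summaries_to_frame(summaries: list[DistanceSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "genotype": s.genotype, "stage_class": s.stage_class,
        "ps_label": s.ps_label, "pair": s.pair,
        "median_nm": s.median, "q1_nm": s.quartiles[0], "q3_nm": s.quartiles[1],
        "n_distances": len(s.pooled), "n_embryos": s.n_embryos,
        "mean_embryo_median_nm": float(np.mean(s.per_embryo_medians)),
        "sem_nm": s.sem,
    } for s in summaries])
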