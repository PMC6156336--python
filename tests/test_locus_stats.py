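import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import random_spots
from hoxfish.locus_stats import (compare_medians_ttest, compare_pooled,
                                 differential_effect, differential_scatter,
                                 expression_distance_correlation,
                                 mean_proximity_fraction, proximity_fraction,
                                 summarize_distances)
from hoxfish.spots import Spot
from test_expression import _exact_mwu_two_tailed


def _distance_frame(rows):
    return pd.DataFrame(rows, columns=["embryo_id", "ps_label", "pair",
                                       "distance_nm"])


class TestSummaries:
    def test_single_embryo_median_and_pooled(self):
        frame = _distance_frame([("e1", "PS0", "ab", d) for d in (100, 200, 300)])
        s = summarize_distances(frame)[0]
        assert s.median == 200.0
        np.testing.assert_array_equal(np.sort(s.pooled), [100, 200, 300])
        assert s.n_embryos == 1 and s.sem is None  # SEM undefined for n = 1

    def test_sem_over_embryo_medians(self):
        rows = [(f"e{i}", "PS0", "ab", v) for i, v in enumerate((200, 300, 400))]
        s = summarize_distances(_distance_frame(rows))[0]
        assert np.mean(s.per_embryo_medians) == 300.0
        assert s.sem == pytest.approx(57.735, abs=1e-3)  # sd 100 / sqrt(3)

    def test_grouping_by_metadata(self):
        frame = _distance_frame([("e1", "PS0", "ab", 100), ("e2", "PS0", "ab", 500)])
        meta = pd.DataFrame({"embryo_id": ["e1", "e2"],
                             "genotype": ["WT", "ph_del"],
                             "stage_class": ["3:50-4:50"] * 2})
        out = summarize_distances(frame, meta)
        assert {s.genotype for s in out} == {"WT", "ph_del"}

    def test_simulated_law_median_recovered(self, small_clean_config):
        from hoxfish.simulate import simulate_distance_table

        cfg = small_clean_config(seed=21, nuclei_per_ps=40)
        table = simulate_distance_table(cfg, n_embryos=20)
        out = summarize_distances(table, grouping=("ps_label", "pair"))
        by_key = {(s.ps_label, s.pair): s.median for s in out}
        assert by_key[("compact", "ab")] == pytest.approx(350, abs=15)
        assert by_key[("open", "ab")] == pytest.approx(700, abs=15)


class TestMannWhitney:
    def test_identical_lists_not_significant(self):
        res = compare_pooled([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.9
        assert res.stars == "ns"

    def test_exact_small_sample_p(self):
        # fully separated 3 vs 3: U = 0, two-tailed p = 2/C(6,3) = 0.1
        res = compare_pooled([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_needs_two_per_side(self):
        with pytest.raises(ValueError):
            compare_pooled([1.0], [1, 2, 3])

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 5), (8, 8), (5, 8)])
    def test_matches_exact_enumeration(self, na, nb, rng):
        for _ in range(6):
            a = list(rng.normal(0, 1, na))
            b = list(rng.normal(0.5, 1, nb))
            res = compare_pooled(a, b)
            assert res.p_value == pytest.approx(_exact_mwu_two_tailed(a, b))

    def test_agrees_with_scipy_reference(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.4, 1, 25)
        res = compare_pooled(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_star_thresholds(self):
        a = np.arange(20.0)
        b = a + 100.0
        assert compare_pooled(a, b).stars == "***"


class TestWelch:
    def test_identical_samples_p_half(self):
        res = compare_medians_ttest([1, 1, 1], [1, 1, 1])
        assert res.p_value == 0.5

    def test_separated_samples_p_tiny(self):
        res = compare_medians_ttest([100, 100.1, 99.9], [1, 1.1, 0.9],
                                    alternative="greater")
        assert res.p_value < 1e-6

    def test_matches_textbook_welch(self, rng):
        a = rng.normal(5, 2, 12)
        b = rng.normal(4, 1, 9)
        res = compare_medians_ttest(a, b, alternative="greater")
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(sps.t.sf(t, df))


class TestDifferentialEffect:
    def _summary(self, genotype, stage, median):
        frame = _distance_frame([("e1", "PS0", "ab", median)] * 3)
        s = summarize_distances(frame)[0]
        s.genotype, s.stage_class = genotype, stage
        return s

    def test_equal_medians_give_zero(self):
        delta = differential_effect([self._summary("ph_del", "3:50-4:50", 450)],
                                    [self._summary("ph_control", "3:50-4:50", 450)])
        assert delta.delta_median_nm.tolist() == [0.0]

    def test_arithmetic(self):
        delta = differential_effect([self._summary("ph_del", "3:50-4:50", 600)],
                                    [self._summary("ph_control", "3:50-4:50", 450)])
        assert delta.delta_median_nm.tolist() == [150.0]

    def test_unmatched_cell_omitted(self):
        delta = differential_effect([self._summary("ph_del", "6:00-7:20", 600)],
                                    [self._summary("ph_control", "3:50-4:50", 450)])
        assert len(delta) == 0

    def test_stage_ordering(self):
        mut = [self._summary("m", s, 500) for s in
               ("7:20-12:00", "3:50-4:50", "6:00-7:20")]
        ctl = [self._summary("c", s, 400) for s in
               ("3:50-4:50", "6:00-7:20", "7:20-12:00")]
        delta = differential_effect(mut, ctl)
        assert delta.stage_class.tolist() == ["3:50-4:50", "6:00-7:20", "7:20-12:00"]


class TestProximity:
    def test_coincident_spots_hundred_percent(self):
        spots = [Spot("g", (i * 10.0, 0, 0), 1, 1, "PS0") for i in range(5)]
        foci = [Spot("Pc", (i * 10.0, 0, 0), 1, 1) for i in range(5)]
        assert proximity_fraction(spots, foci) == {"PS0": 100.0}

    def test_all_beyond_cutoff_zero_percent(self):
        spots = [Spot("g", (0.0, 0, 0), 1, 1, "PS0")]
        foci = [Spot("Pc", (500.0, 0, 0), 1, 1)]
        assert proximity_fraction(spots, foci) == {"PS0": 0.0}

    def test_no_foci_is_error(self):
        with pytest.raises(ValueError):
            proximity_fraction([Spot("g", (0, 0, 0), 1, 1, "PS0")], [])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            spots = random_spots(rng, 30)
            for i, s in enumerate(spots):
                s.ps_label = f"PS{i % 3}"
            foci = random_spots(rng, 10)
            got = proximity_fraction(spots, foci, cutoff_nm=1200.0)
            expected = {}
            for s in spots:
                d = min(np.linalg.norm(s.xyz - f.xyz) for f in foci)
                expected.setdefault(s.ps_label, []).append(d < 1200.0)
            expected = {ps: 100.0 * np.mean(v) for ps, v in expected.items()}
            assert got == pytest.approx(expected)

    def test_mean_across_embryos(self):
        out = mean_proximity_fraction([{"PS0": 40.0}, {"PS0": 60.0, "PS1": 10.0}])
        assert out == {"PS0": 50.0, "PS1": 10.0}


class TestCorrelationMap:
    AXIS = [f"PS{i}" for i in range(6)]

    def test_identical_series_r_one(self):
        s = pd.Series([1, 2, 3, 4, 5, 6.0], index=self.AXIS)
        assert expression_distance_correlation(s, s).r == pytest.approx(1.0)

    def test_reversed_monotone_series_r_minus_one(self):
        s = pd.Series([1, 2, 3, 4, 5, 6.0], index=self.AXIS)
        rev = pd.Series(s.values[::-1], index=self.AXIS)
        assert expression_distance_correlation(s, rev).r == pytest.approx(-1.0)

    def test_axis_mismatch_lists_missing(self):
        s = pd.Series([1, 2, 3.0], index=["PS0", "PS1", "PS2"])
        t = pd.Series([1, 2, 3.0], index=["PS0", "PS1", "PS9"])
        with pytest.raises(ValueError, match="PS9"):
            expression_distance_correlation(s, t)

    def test_r_matches_covariance_formula(self, rng):
        d = pd.Series(rng.uniform(200, 900, 6), index=self.AXIS)
        e = pd.Series(rng.uniform(0, 1, 6), index=self.AXIS)
        cm = expression_distance_correlation(d, e)
        x, y = cm.dist_norm, cm.exp_norm
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert cm.r == pytest.approx(expected)
        assert np.all((x >= 0) & (x <= 1)) and np.all((y >= 0) & (y <= 1))


class TestDifferentialScatter:
    def test_linear_relation_r_one(self):
        x = pd.Series([1.0, 2, 3, 4], index=["PS0", "PS1", "PS2", "PS3"])
        points, r = differential_scatter(x, 2 * x)
        assert len(points) == 4
        assert r == pytest.approx(1.0)

    def test_too_few_shared_ps_gives_no_r(self):
        x = pd.Series([1.0, 2], index=["PS0", "PS1"])
        points, r = differential_scatter(x, x)
        assert len(points) == 2 and r is None

    def test_permutation_null_mean_r_near_zero(self, rng):
        x = pd.Series(rng.normal(0, 1, 8), index=[f"PS{i}" for i in range(8)])
        rs = []
        for _ in range(500):
            y = pd.Series(rng.permutation(x.values), index=x.index)
            _, r = differential_scatter(x, y)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05


@given(st.lists(st.floats(min_value=0, max_value=1500), min_size=4, max_size=30),
       st.lists(st.floats(min_value=0, max_value=1500), min_size=4, max_size=30))
def test_pooled_support_preserved(a, b):
    """Summaries of distances in [0, 1500] stay in [0, 1500]."""
    frame = _distance_frame(
        [("e1", "PS0", "ab", v) for v in a] + [("e2", "PS0", "ab", v) for v in b])
    s = summarize_distances(frame)[0]
    assert 0 <= s.median <= 1500
    assert 0 <= s.quartiles[0] <= s.quartiles[1] <= 1500
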