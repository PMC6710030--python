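import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import spinecongruence as sc
from spinecongruence.errors import SpineCongruenceError


class TestAnova:
    def test_hand_computed_two_groups(self):
        # SSB = 4, SSW = 1, MSW = 0.5 -> F = 8
        res = sc.anova_oneway([[1, 2], [3, 4]])
        assert res.F == pytest.approx(8.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 2)
        assert 0 <= res.p <= 1

    def test_identical_groups_f_zero(self):
        res = sc.anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0
        assert res.p == pytest.approx(1.0)

    def test_one_group_rejected(self):
        with pytest.raises(SpineCongruenceError):
            sc.anova_oneway([[1, 2, 3]])

    def test_zero_within_variance_rejected(self):
        with pytest.raises(SpineCongruenceError):
            sc.anova_oneway([[1, 1], [2, 2]])

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1.0, 30) for m in (0.0, 0.3, 0.8)]
        res = sc.anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        res = sc.anova_oneway([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t.statistic**2, abs=1e-9)


class TestTukey:
    def test_identical_groups_all_null(self):
        pairs = sc.tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert len(pairs) == 3
        for c in pairs:
            assert c.mean_difference == 0.0
            assert c.p == pytest.approx(1.0)
            assert not c.significant

    def test_k2_equals_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 17)
        (cmp,) = sc.tukey_hsd([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert cmp.q == pytest.approx(abs(t.statistic) * np.sqrt(2), rel=1e-12)
        assert cmp.p == pytest.approx(t.pvalue, abs=1e-6)

    def test_separated_groups_all_flagged(self):
        groups = [[0, 0.01, -0.01], [10, 10.01, 9.99], [20, 19.99, 20.01]]
        pairs = sc.tukey_hsd(groups, alpha=0.05)
        assert all(c.significant for c in pairs)
        assert all(c.q > 100 for c in pairs)

    def test_matches_scipy_tukey(self, rng):
        groups = [rng.normal(m, 1.0, 15) for m in (0.0, 0.4, 0.9)]
        ours = sc.tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for c in ours:
            i, j = c.pair
            assert c.p == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_relabel_and_shift_invariance(self, rng):
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.5, 1.2)]
        base = {frozenset(c.pair): c.p for c in sc.tukey_hsd(groups)}
        perm = [groups[2], groups[0], groups[1]]
        relabeled = sc.tukey_hsd(perm)
        assert sorted(base.values()) == pytest.approx(
            sorted(c.p for c in relabeled), rel=1e-12
        )
        shifted = sc.tukey_hsd([g + 5.0 for g in groups])
        for c0, c1 in zip(sc.tukey_hsd(groups), shifted):
            assert c0.p == pytest.approx(c1.p, rel=1e-12)


class TestLevene:
    def test_equal_deviations_give_zero(self):
        w, p = sc.levene([[0, 2], [5, 7]])
        assert w == 0.0
        assert p == 1.0

    def test_unequal_spread_detected(self):
        w, p = sc.levene([[0, 2], [-10, 10]])
        assert w > 0
        assert p < 1.0

    def test_single_observation_rejected(self):
        with pytest.raises(SpineCongruenceError):
            sc.levene([[1], [2]])

    def test_location_shift_invariance(self, rng):
        groups = [rng.normal(0, s, 25) for s in (1.0, 2.5)]
        w0, p0 = sc.levene(groups)
        w1, p1 = sc.levene([g + 100.0 for g in groups])
        assert w0 == pytest.approx(w1, rel=1e-9)
        assert p0 == pytest.approx(p1, rel=1e-9)

    def test_matches_scipy_levene(self, rng):
        groups = [rng.normal(0, s, 30) for s in (1.0, 1.2, 3.0)]
        w, p = sc.levene(groups)
        ref = sps.levene(*groups, center="mean")
        assert w == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)


class TestSummarize:
    def test_two_value_cell(self):
        df = pd.DataFrame(dict(group=["A", "A"], shape=["plane"] * 2, itpr=[0.4, 0.6]))
        out = sc.summarize(df, by=["group", "shape"])
        cell = out.loc[("A", "plane")]
        assert cell["mean"] == pytest.approx(0.5)
        assert cell["sd"] == pytest.approx(0.14142135, abs=1e-6)
        assert not cell["degenerate"]

    def test_single_record_degenerate(self):
        df = pd.DataFrame(dict(group=["A"], itpr=[0.4]))
        out = sc.summarize(df, by=["group"])
        assert out.loc["A", "sd"] == 0.0
        assert bool(out.loc["A", "degenerate"])

    def test_empty_rejected(self):
        with pytest.raises(SpineCongruenceError):
            sc.summarize(pd.DataFrame(columns=["group", "itpr"]), by=["group"])
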