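"""Statistical primitives: DE t-tests, one-way ANOVA F, BH, hypergeometric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from dcnet import stats
from conftest import make_study


class TestDePvalues:
    def test_paired_t_matches_closed_form(self):
        # paired differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        base = np.array([[0.0, 0.0, 0.0]])
        treat = base + np.array([[1.0, 2.0, 3.0]])
        study = make_study(np.hstack([base, treat]))
        p = stats.de_pvalues(study, method="paired_t")["G0000"]
        assert p == pytest.approx(0.0742, abs=1e-3)
        t_oracle = 2.0 / (1.0 / np.sqrt(3.0))
        assert p == pytest.approx(2 * sps.t.sf(t_oracle, df=2), rel=1e-12)

    def test_identical_matrices_give_p_one(self):
        block = np.arange(12.0).reshape(3, 4)
        study = make_study(np.hstack([block, block]))
        assert all(p == 1.0 for p in stats.de_pvalues(study, "paired_t").values())

    def test_welch_equal_groups_give_p_one(self):
        vals = np.array([[0.0, 1.0, 0.0, 1.0]])
        study = make_study(vals)
        assert stats.de_pvalues(study, "welch_t")["G0000"] == 1.0

    def test_broken_pairing_raises(self):
        from dcnet import ExpressionStudy

        study = ExpressionStudy(
            ["g1"], np.zeros((1, 4)), ["a", "b", "c", "d"],
            {"a": "baseline", "b": "baseline", "c": "treated", "d": "treated"},
            {"a": "p1", "b": "p2", "c": "p1", "d": "p3"},
        )
        with pytest.raises(ValueError, match="both conditions"):
            stats.de_pvalues(study, "paired_t")

    def test_unknown_method_raises(self):
        study = make_study(np.zeros((1, 4)))
        with pytest.raises(ValueError, match="unknown"):
            stats.de_pvalues(study, "moderated")


class TestAnovaF:
    def test_hand_computed_example(self):
        # groups (0,1) and (2,3): MSS = 4, RSS = 0.5 -> F = 8
        study = make_study(np.array([[0.0, 1.0, 2.0, 3.0]]))
        assert stats.anova_f(study)["G0000"] == pytest.approx(8.0, abs=1e-12)

    def test_constant_gene_flagged_zero(self):
        study = make_study(np.full((1, 6), 3.5))
        res = stats.anova_f(study)
        assert res["G0000"] == 0.0
        assert "G0000" not in res.infinite

    def test_zero_residual_flagged_infinite(self):
        study = make_study(np.array([[1.0, 1.0, 2.0, 2.0]]))
        res = stats.anova_f(study)
        assert np.isinf(res["G0000"])
        assert "G0000" in res.infinite

    def test_equals_squared_t_for_two_groups(self, rng):
        vals = rng.normal(size=(200, 10))
        study = make_study(vals)
        res = stats.anova_f(study)
        t = sps.ttest_ind(vals[:, :5], vals[:, 5:], axis=1, equal_var=True).statistic
        f = np.array([res[g] for g in study.gene_ids])
        assert np.max(np.abs(f - t**2)) < 1e-9

    def test_matches_scipy_f_oneway(self, rng):
        vals = rng.normal(size=(50, 9))
        study = make_study(vals, n_baseline=4)
        res = stats.anova_f(study)
        oracle = sps.f_oneway(vals[:, :4], vals[:, 4:], axis=1).statistic
        assert np.allclose([res[g] for g in study.gene_ids], oracle, atol=1e-9)

    def test_too_few_samples_raises(self):
        study = make_study(np.zeros((1, 2)))
        with pytest.raises(ValueError, match="residual df"):
            stats.anova_f(study)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04, 0.05], [0.05] * 5),
            ([0.2], [0.2]),
            ([0.05, 0.01], [0.05, 0.02]),
        ],
    )
    def test_step_up_examples(self, raw, expected):
        assert stats.bh_adjust(raw) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = stats.bh_adjust(p)
            oracle = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, oracle, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_adjustment_properties(self, pvals):
        adj = np.array(stats.bh_adjust(pvals))
        p = np.array(pvals)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # step-up monotonicity: adjusted values ordered like the raw ranks
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestHypergeom:
    def test_total_overlap_small_universe(self):
        # P(X >= 5) with K = n = 5, N = 10 is 1/C(10,5) = 1/252
        assert stats.hypergeom_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_is_one(self):
        assert stats.hypergeom_pvalue(0, 5, 5, 100) == pytest.approx(1.0)

    def test_forced_total_overlap_is_one(self):
        assert stats.hypergeom_pvalue(5, 5, 5, 5) == pytest.approx(1.0)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError, match="inconsistent"):
            stats.hypergeom_pvalue(6, 5, 5, 10)


class TestWelch:
    def test_printed_toy_vectors(self):
        t, df, p = stats.welch_t_test([3, 4, 5], [0, 1, 2])
        assert t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-9)
        assert df == pytest.approx(4.0, rel=1e-9)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_identical_samples(self):
        t, _, p = stats.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=9)
        t1, df1, p1 = stats.welch_t_test(a, b)
        t2, df2, p2 = stats.welch_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2) and df1 == pytest.approx(df2)

    def test_degenerate_variance(self):
        t, _, p = stats.welch_t_test([2.0, 2.0], [5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy(self, rng):
        a, b = rng.normal(size=7), rng.normal(1.0, 2.0, size=12)
        t, df, p = stats.welch_t_test(a, b)
        oracle = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(oracle.statistic, rel=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-9)
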