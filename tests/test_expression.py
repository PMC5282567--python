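import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from cernet.expression import (ExpressionMatrix, bh_adjust, call_de,
                               candidate_filter, de_test,
                               differential_expression, fpkm,
                               lowess_normalize, pool_samples)
from oracles import exact_mannwhitney_enumeration, naive_bh


def make_matrix(case, control, feature_class="mrna", features=None):
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n_feat = case.shape[0]
    features = features or [f"f{i}" for i in range(n_feat)]
    samples = [f"c{i}" for i in range(case.shape[1])] + \
              [f"k{i}" for i in range(control.shape[1])]
    values = pd.DataFrame(np.hstack([case, control]), index=features, columns=samples)
    groups = pd.Series(["case"] * case.shape[1] + ["control"] * control.shape[1],
                       index=samples)
    return ExpressionMatrix(values, groups, feature_class)


class TestExpressionMatrix:
    def test_rejects_duplicate_and_negative(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        groups = pd.Series({"s1": "case", "s2": "control"})
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(values - 5, groups, "mrna")
        dup = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "a"],
                           columns=["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate feature"):
            ExpressionMatrix(dup, groups, "mrna")
        with pytest.raises(ValueError, match="at least one"):
            ExpressionMatrix(values, pd.Series({"s1": "case", "s2": "case"}), "mrna")

    def test_tsv_round_trip(self, tmp_path):
        m = make_matrix([[1.5, 2.5], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]])
        m.to_tsv(tmp_path / "e.tsv", tmp_path / "g.tsv")
        back = ExpressionMatrix.from_tsv(tmp_path / "e.tsv", tmp_path / "g.tsv", "mrna")
        pd.testing.assert_frame_equal(m.values, back.values)
        assert list(back.groups) == list(m.groups)

    def test_pooling_collapses_to_group_means(self):
        m = make_matrix([[2.0, 4.0]], [[1.0, 3.0]])
        pooled = pool_samples(m)
        assert pooled.values.loc["f0", "case_pool"] == 3.0
        assert pooled.values.loc["f0", "control_pool"] == 2.0


class TestFpkm:
    def test_worked_example(self):
        counts = pd.DataFrame({"s": [100, 0]}, index=["g1", "g2"])
        out = fpkm(counts, pd.Series({"g1": 1000, "g2": 500}),
                   pd.Series({"s": 1_000_000}))
        assert out.loc["g1", "s"] == pytest.approx(100.0)
        assert out.loc["g2", "s"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [50, 7], "s2": [50, 7]}, index=["g1", "g2"])
        out = fpkm(counts, pd.Series({"g1": 800, "g2": 1200}),
                   pd.Series({"s1": 1e6, "s2": 2e6}))
        assert np.allclose(out["s1"], 2 * out["s2"])
        assert list(out.index) == ["g1", "g2"]  # ordering preserved

    def test_rejects_zero_length_or_library(self):
        counts = pd.DataFrame({"s": [1]}, index=["g"])
        with pytest.raises(ValueError, match="lengths"):
            fpkm(counts, pd.Series({"g": 0}), pd.Series({"s": 1e6}))
        with pytest.raises(ValueError, match="library"):
            fpkm(counts, pd.Series({"g": 100}), pd.Series({"s": 0}))


class TestLowess:
    def test_identity_when_channels_equal(self, rng):
        signal = 2.0 ** rng.uniform(4, 12, size=200)
        out_case, out_control = lowess_normalize(signal, signal)
        assert np.allclose(out_case, signal, rtol=1e-9)
        assert np.allclose(out_control, signal, rtol=1e-9)

    def test_constant_log_ratio_removed(self, rng):
        control = 2.0 ** rng.uniform(4, 12, size=300)
        case = control * 2.0 ** 1.7
        out_case, out_control = lowess_normalize(case, control)
        m = np.log2(out_case) - np.log2(out_control)
        assert np.max(np.abs(m)) < 1e-6

    def test_curved_intensity_bias_removed(self, rng):
        a = rng.uniform(5, 12, size=2000)
        m_bias = 0.4 * np.sin(a / 2.0) + 0.2
        case = 2.0 ** (a + m_bias / 2)
        control = 2.0 ** (a - m_bias / 2)
        out_case, out_control = lowess_normalize(case, control)
        m = np.log2(out_case) - np.log2(out_control)
        assert abs(np.median(m)) < 0.01

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            lowess_normalize(np.ones(5), np.ones(5))


class TestDeTest:
    def test_identical_groups_all_ties_p_one(self):
        m = make_matrix([[5.0, 5.0, 5.0]], [[5.0, 5.0, 5.0]])
        p = de_test(m, method="mann_whitney")
        assert p.iloc[0] == 1.0

    def test_exact_mannwhitney_matches_enumeration(self):
        cases = [([1, 2, 3], [4, 5, 6]),          # fully separated: p = 2/20
                 ([1, 5, 3], [2, 4, 6]),
                 ([1, 1, 2, 3], [2, 2, 3, 4])]    # ties across groups
        for x, y in cases:
            m = make_matrix([list(map(float, x))], [list(map(float, y))])
            p = de_test(m, method="mann_whitney").iloc[0]
            assert p == pytest.approx(exact_mannwhitney_enumeration(x, y), abs=1e-12)

    def test_separated_groups_exact_p(self):
        m = make_matrix([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        assert de_test(m, method="mann_whitney").iloc[0] == pytest.approx(0.1)

    def test_welch_type_i_error_calibrated(self, rng):
        reps, n = 10_000, 10
        case = 2.0 ** rng.normal(8, 1, size=(reps, n))
        control = 2.0 ** rng.normal(8, 1, size=(reps, n))
        from scipy.stats import ttest_ind
        p = ttest_ind(np.log2(case), np.log2(control), axis=1, equal_var=False).pvalue
        # sanity-bound for the simulation itself
        assert abs((p < 0.05).mean() - 0.05) < 0.01
        # and the package path agrees with scipy on a slice of them
        # (accounting for the documented half-min-positive pseudocount)
        m = make_matrix(case[:50], control[:50])
        pc = 0.5 * np.min(np.hstack([case[:50], control[:50]]))
        ref = ttest_ind(np.log2(case[:50] + pc), np.log2(control[:50] + pc),
                        axis=1, equal_var=False).pvalue
        ours = de_test(m, method="welch_t_on_log2")
        assert np.allclose(ours.to_numpy(), ref, atol=1e-12)

    def test_single_group_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["s1", "s2"])
        groups = pd.Series({"s1": "case", "s2": "control"})
        m = ExpressionMatrix(values, groups, "mrna")
        with pytest.raises(ValueError):
            de_test(m, method="welch_t_on_log2")


class TestBhAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_naive_definition_and_statsmodels(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 60))
            q = bh_adjust(p)
            assert np.max(np.abs(q - np.array(naive_bh(p)))) < 1e-12
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sorted_order_and_bounded(self, pvals):
        q = bh_adjust(pvals)
        assert ((q >= np.asarray(pvals) - 1e-15) & (q <= 1.0)).all()
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust([0.1, np.nan])


class TestSelection:
    @staticmethod
    def table(**overrides):
        row = dict(feature="f", feature_class="mrna", mean_case=100.0,
                   mean_control=25.0, fc=4.0, log2fc=2.0, p=0.001, q=0.01,
                   direction="up", max_group_signal=100.0, passes_de=True,
                   passes_candidate=True)
        row.update(overrides)
        return pd.DataFrame([row])

    def test_call_de_thresholds_are_strict(self):
        up, down = call_de(self.table(log2fc=1.1, q=0.01))
        assert up == {"f"} and not down
        up, down = call_de(self.table(log2fc=1.1, q=0.05))
        assert not up and not down  # q threshold strict
        up, down = call_de(self.table(log2fc=1.0, q=0.01))
        assert not up  # fold-change threshold strict
        up, down = call_de(self.table(log2fc=-1.2, q=0.04))
        assert down == {"f"}

    def test_all_q_one_selects_nothing(self):
        up, down = call_de(self.table(q=1.0))
        assert not up and not down

    def test_candidate_signal_floor_microarray(self):
        t = self.table(feature_class="mirna", max_group_signal=499.0)
        assert candidate_filter(t) == set()
        t = self.table(feature_class="mirna", max_group_signal=500.0)
        assert candidate_filter(t) == {"f"}

    def test_candidate_copy_floor_uses_either_group(self):
        # FPKM 30 in one group only still counts (max over groups)
        t = self.table(feature_class="lncrna", mean_case=30.0, mean_control=1.0,
                       max_group_signal=30.0, log2fc=2.0, p=0.001)
        assert candidate_filter(t) == {"f"}

    def test_candidate_log2fc_floor_strict(self):
        t = self.table(log2fc=1.5)
        assert candidate_filter(t) == set()

    def test_candidate_requires_nonzero_p(self):
        t = self.table(p=0.0)
        assert candidate_filter(t) == set()


class TestDifferentialExpression:
    def test_direction_sets_disjoint_and_fc_identity(self, rng):
        case = 2.0 ** rng.normal(8, 1, size=(100, 6))
        control = 2.0 ** rng.normal(8, 1, size=(100, 6))
        case[:10] *= 8.0
        m = make_matrix(case, control)
        table = differential_expression(m)
        up, down = call_de(table)
        assert not (up & down)
        assert np.allclose(table["fc"], 2.0 ** table["log2fc"], rtol=1e-9)
        assert (table["q"] >= table["p"] - 1e-15).all()
        assert list(table["feature"]) == list(m.values.index)

    def test_zero_mean_feature_keeps_finite_fc(self):
        m = make_matrix([[0.0, 0.0, 0.0], [10.0, 12.0, 11.0]],
                        [[4.0, 5.0, 6.0], [10.0, 12.0, 11.0]])
        table = differential_expression(m)
        assert np.isfinite(table["fc"]).all()
        assert table.loc[0, "fc"] < 1.0
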