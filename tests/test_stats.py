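import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from trnacharge.stats import (
    StatsError,
    bh_adjust,
    compare_conditions,
    ddct,
    fraction_charged,
    normalize,
    summarize_replicates,
    welch_test,
)


def _counts(rows):
    return pd.DataFrame(
        rows, columns=["sample", "gene", "n_charged", "n_uncharged", "n_undetermined"]
    )


class TestNormalize:
    def test_coefficients_from_classified_totals(self):
        counts = _counts(
            [("a", "g", 60, 40, 5), ("b", "g", 150, 50, 0), ("c", "g", 200, 100, 9)]
        )
        norm, coeff = normalize(counts)
        assert coeff.tolist() == [2.0, 1.0, pytest.approx(2 / 3)]
        totals = norm.groupby("sample")[["n_charged", "n_uncharged"]].sum().sum(axis=1)
        assert np.allclose(totals, 200.0, rtol=1e-9)

    def test_equal_totals_identity(self):
        counts = _counts([("a", "g", 50, 50, 0), ("b", "g", 70, 30, 0)])
        _, coeff = normalize(counts)
        assert (coeff == 1.0).all()

    def test_single_sample_coefficient_one(self):
        _, coeff = normalize(_counts([("a", "g", 10, 5, 0)]))
        assert coeff.tolist() == [1.0]

    def test_zero_classified_sample_is_hard_error(self):
        counts = _counts([("a", "g", 0, 0, 7), ("b", "g", 5, 5, 0)])
        with pytest.raises(StatsError, match="a"):
            normalize(counts)


class TestFractionCharged:
    ISO = {"g1": "His-GTG", "g2": "His-GTG", "g3": "Leu-CAA"}

    def test_sums_genes_within_isodecoder(self):
        counts = _counts([("a", "g1", 30, 10, 0), ("a", "g2", 10, 10, 0)])
        fr = fraction_charged(counts, self.ISO)
        assert fr.loc["a", "His-GTG"] == pytest.approx(40 / 60)

    def test_all_charged_is_one(self):
        fr = fraction_charged(_counts([("a", "g1", 25, 0, 0)]), self.ISO)
        assert fr.loc["a", "His-GTG"] == 1.0

    def test_zero_coverage_is_missing_not_zero(self):
        counts = _counts([("a", "g1", 5, 5, 0), ("a", "g3", 0, 0, 2)])
        fr = fraction_charged(counts, self.ISO)
        assert np.isnan(fr.loc["a", "Leu-CAA"])

    def test_unknown_gene_rejected(self):
        with pytest.raises(StatsError):
            fraction_charged(_counts([("a", "gX", 1, 1, 0)]), self.ISO)

    def test_invariant_to_normalization(self):
        rng = np.random.default_rng(0)
        rows = [
            (s, g, int(rng.integers(1, 500)), int(rng.integers(1, 500)), 0)
            for s in "abcd" for g in self.ISO
        ]
        counts = _counts(rows)
        norm, _ = normalize(counts)
        raw = fraction_charged(counts, self.ISO)
        nrm = fraction_charged(norm, self.ISO)
        assert np.allclose(raw.to_numpy(), nrm.to_numpy(), rtol=0, atol=1e-12)


class TestSummarizeReplicates:
    DESIGN = pd.DataFrame(
        {"sample": ["a", "b", "c", "d"], "condition": ["x", "x", "y", "y"]}
    )

    def test_mean_and_sample_sd(self):
        fr = pd.DataFrame({"His-GTG": [0.5, 0.7, 0.4, 0.4]},
                          index=["a", "b", "c", "d"])
        out = summarize_replicates(fr, self.DESIGN).set_index("condition")
        assert out.loc["x", "mean"] == pytest.approx(0.6)
        assert out.loc["x", "sd"] == pytest.approx(0.14142135623730953)
        assert out.loc["y", "sd"] == 0.0

    def test_missing_replicate_excluded(self):
        fr = pd.DataFrame({"His-GTG": [0.5, np.nan, 0.4, 0.4]},
                          index=["a", "b", "c", "d"])
        out = summarize_replicates(fr, self.DESIGN).set_index("condition")
        assert out.loc["x", "n"] == 1
        assert out.loc["x", "mean"] == pytest.approx(0.5)
        assert np.isnan(out.loc["x", "sd"])


class TestWelch:
    def test_matches_scipy_reference(self):
        a, b = [1, 2, 3, 4], [2, 4, 6, 8]
        r = welch_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert r.df == pytest.approx(ref.df, abs=1e-10)

    def test_identical_groups_null(self):
        r = welch_test([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        r1 = welch_test([1, 2, 3], [4, 5, 7])
        r2 = welch_test([4, 5, 7], [1, 2, 3])
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_zero_variance(self):
        same = welch_test([0.5, 0.5], [0.5, 0.5])
        assert same.t == 0.0 and same.p == 1.0 and not same.degenerate
        diff = welch_test([0.5, 0.5], [0.7, 0.7])
        assert diff.p == 0.0 and diff.degenerate

    def test_single_value_group_rejected(self):
        with pytest.raises(StatsError):
            welch_test([1.0], [1.0, 2.0])


class TestBH:
    def test_step_up_equalises_arithmetic_ladder(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_bounded(self, ps):
        out = bh_adjust(ps)
        assert (out >= np.asarray(ps) - 1e-15).all()
        assert (out <= 1.0).all()

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2]]).any()


class TestDdct:
    def _frame(self, treated, control):
        rows = []
        for i, (t, r) in enumerate(treated):
            rows.append(("t%d" % i, "treated", t, r))
        for i, (t, r) in enumerate(control):
            rows.append(("c%d" % i, "control", t, r))
        return pd.DataFrame(rows, columns=["sample", "group", "ct_target",
                                           "ct_reference"])

    def test_worked_example_fourfold(self):
        df = self._frame([(20, 15)], [(22, 15)])
        out = ddct(df, "control")
        treated = out[out["group"] == "treated"].iloc[0]
        assert treated["ddct"] == pytest.approx(-2.0)
        assert treated["relative_abundance"] == pytest.approx(4.0)

    def test_treated_equals_control_is_unity(self):
        df = self._frame([(21, 16)], [(21, 16)])
        out = ddct(df, "control")
        assert (out["relative_abundance"] == 1.0).all()

    def test_one_cycle_up_halves_abundance(self):
        df = self._frame([(23, 15)], [(22, 15)])
        out = ddct(df, "control")
        treated = out[out["group"] == "treated"].iloc[0]
        assert treated["relative_abundance"] == pytest.approx(0.5)

    def test_missing_reference_ct_rejected(self):
        df = self._frame([(20, np.nan)], [(22, 15)])
        with pytest.raises(StatsError):
            ddct(df, "control")


class TestCompareConditions:
    def test_bh_within_contrast_and_welch_values(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(8)]
        design = pd.DataFrame(
            {"sample": samples, "condition": ["x"] * 4 + ["y"] * 4}
        )
        fr = pd.DataFrame(
            rng.uniform(0.5, 1.0, size=(8, 6)),
            index=samples, columns=[f"iso{i}" for i in range(6)],
        )
        res = compare_conditions(fr, design, [("x", "y")])
        assert len(res) == 6
        for _, row in res.iterrows():
            a = fr.loc[samples[:4], row["isodecoder"]]
            b = fr.loc[samples[4:], row["isodecoder"]]
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert row["t"] == pytest.approx(ref.statistic, abs=1e-10)
        assert np.allclose(
            res["p_adj"].to_numpy(), bh_adjust(res["p"].to_numpy()), atol=1e-12
        )
        assert (res["p_adj"] >= res["p"] - 1e-15).all()

    def test_insufficient_replicates_yield_nan_row(self):
        design = pd.DataFrame(
            {"sample": ["a", "b", "c", "d"], "condition": ["x", "x", "y", "y"]}
        )
        fr = pd.DataFrame({"iso": [0.5, np.nan, 0.6, 0.7]},
                          index=["a", "b", "c", "d"])
        res = compare_conditions(fr, design, [("x", "y")])
        assert np.isnan(res.iloc[0]["p"])

    def test_unknown_condition_rejected(self):
        design = pd.DataFrame({"sample": ["a"], "condition": ["x"]})
        fr = pd.DataFrame({"iso": [0.5]}, index=["a"])
        with pytest.raises(StatsError):
            compare_conditions(fr, design, [("x", "zzz")])
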