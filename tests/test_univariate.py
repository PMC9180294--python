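"""The univariate battery: LME, BH-FDR, fold change, ROC AUC + CI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from berrystage import univariate
from berrystage.univariate import (
    auc_ci,
    benjamini_hochberg,
    fold_change,
    lme_stage_test,
    roc_auc,
    table_summary,
)


def brute_force_auc(pos, neg):
    """Oracle: enumerate all pairs, count wins and half-ties."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLmeStageTest:
    def test_balanced_reduces_to_ttest_on_sample_means(self, rng):
        """With a balanced design the Wald t with between-sample df equals
        the two-sample t-test on per-sample replicate means."""
        for _ in range(10):
            y = rng.normal(size=60) + np.repeat(rng.normal(0, 1, 10), 6)
            stage = np.repeat(["half-red", "red"], 30)
            sample = np.repeat([f"s{i}" for i in range(10)], 6)
            res = lme_stage_test(y, stage, sample)
            means = [y[sample == f"s{i}"].mean() for i in range(10)]
            ref = stats.ttest_ind(means[5:], means[:5])
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)
            assert res.estimate == pytest.approx(
                np.mean(means[5:]) - np.mean(means[:5]), rel=1e-10
            )

    def test_unbalanced_matches_statsmodels_reml(self, rng):
        """Profiled REML variance components and fixed effect agree with
        statsmodels MixedLM on an unbalanced layout."""
        import statsmodels.formula.api as smf

        reps = [3, 5, 4, 6, 2, 7, 4, 3, 5, 6]
        sample = np.concatenate([[f"s{i}"] * r for i, r in enumerate(reps)])
        stage = np.array(["half-red" if int(s[1:]) < 5 else "red" for s in sample])
        y = (
            rng.normal(size=len(sample))
            + np.concatenate([[rng.normal(0, 1.5)] * r for r in reps])
            + (stage == "red") * 0.8
        )
        res = lme_stage_test(y, stage, sample)
        df = pd.DataFrame({"y": y, "stage": stage, "sample": sample})
        m = smf.mixedlm("y ~ stage", df, groups=df["sample"]).fit(reml=True)
        assert res.estimate == pytest.approx(m.params["stage[T.red]"], rel=1e-4)
        assert res.se == pytest.approx(m.bse["stage[T.red]"], rel=1e-3)
        assert res.sigma2_sample == pytest.approx(m.cov_re.iloc[0, 0], rel=1e-2)
        assert res.sigma2_resid == pytest.approx(m.scale, rel=1e-2)

    def test_parameter_recovery_bias_small(self):
        """Fixed effect and variance components recovered with small bias
        at 200 biological samples."""
        est, s2a, s2e = [], [], []
        for seed in range(30):
            r = np.random.default_rng(seed)
            sample = np.repeat([f"s{i}" for i in range(200)], 5)
            stage = np.repeat(["half-red", "red"], 500)
            y = (
                np.repeat(r.normal(0, np.sqrt(0.9), 200), 5)
                + r.normal(0, np.sqrt(0.1), 1000)
                + (stage == "red") * 1.0
            )
            res = lme_stage_test(y, stage, sample)
            est.append(res.estimate)
            s2a.append(res.sigma2_sample)
            s2e.append(res.sigma2_resid)
        assert abs(np.mean(est) - 1.0) < 0.05
        assert abs(np.mean(s2a) - 0.9) / 0.9 < 0.05
        assert abs(np.mean(s2e) - 0.1) / 0.1 < 0.05

    def test_single_sample_stage_rejected(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            lme_stage_test(y, ["a"] * 4 + ["b"] * 2, ["s1", "s1", "s2", "s2", "s3", "s3"])

    def test_constant_values_rejected(self):
        y = np.ones(8)
        stage = ["a"] * 4 + ["b"] * 4
        sample = ["s1", "s1", "s2", "s2", "s3", "s3", "s4", "s4"]
        with pytest.raises(ValueError, match="variance"):
            lme_stage_test(y, stage, sample)


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        """p = (.001,.02,.03,.04), m=4: all four pass their step-up
        thresholds i*delta/m."""
        adjusted, reject = benjamini_hochberg([0.001, 0.02, 0.03, 0.04])
        assert reject.all()
        np.testing.assert_allclose(adjusted, [0.004, 0.04, 0.04, 0.04])

    def test_uniform_half_none_rejected(self):
        adjusted, reject = benjamini_hochberg([0.5] * 6)
        assert not reject.any()
        np.testing.assert_allclose(adjusted, 0.5)

    def test_single_p_is_identity(self):
        adjusted, reject = benjamini_hochberg([0.04])
        assert adjusted[0] == pytest.approx(0.04)
        assert reject[0]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        adjusted, reject = benjamini_hochberg(p)
        _, adj_ref, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adjusted, adj_ref, atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])


class TestFoldChange:
    def test_published_s1_ratio(self):
        assert round(fold_change([0.408], [0.439]), 3) == 0.929

    def test_published_s7_ratio(self):
        assert round(fold_change([1.930], [1.322]), 3) == 1.460

    def test_identical_groups_unity(self, rng):
        x = rng.normal(size=11)
        assert fold_change(x, x) == pytest.approx(1.0)

    def test_even_n_midpoint_convention(self):
        assert fold_change([1.0, 2.0], [1.0, 1.0]) == pytest.approx(1.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fold_change([1.0], [0.0])


class TestRocAuc:
    def test_perfect_separation(self):
        v = np.r_[np.zeros(5), np.ones(5)]
        lab = np.r_[["half-red"] * 5, ["red"] * 5]
        assert roc_auc(v, lab).auc == 1.0

    def test_permuted_labels_near_half(self, rng):
        v = rng.normal(size=4000)
        lab = rng.permutation(np.r_[["half-red"] * 2000, ["red"] * 2000])
        assert roc_auc(v, lab).auc == pytest.approx(0.5, abs=0.04)

    def test_small_worked_example(self):
        """red=(3,5), half=(1,4): 3 of 4 pairs concordant -> raw 0.75."""
        res = roc_auc([3, 5, 1, 4], ["red", "red", "half-red", "half-red"])
        assert res.raw == pytest.approx(0.75)

    def test_folding_keeps_direction(self):
        res = roc_auc([5, 4, 1, 2], ["half-red", "half-red", "red", "red"])
        assert res.auc == 1.0 and res.raw == 0.0 and res.direction == -1

    def test_rank_formula_equals_brute_force(self, rng):
        """500 random small instances (n <= 12), with ties, against the
        pair-enumeration oracle."""
        for _ in range(500):
            n1, n0 = rng.integers(1, 7, 2)
            v = rng.integers(0, 5, n1 + n0).astype(float)
            lab = np.r_[["red"] * n1, ["half-red"] * n0]
            res = roc_auc(v, lab)
            assert res.raw == pytest.approx(brute_force_auc(v[:n1], v[n1:]), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        v = rng.normal(size=80)
        lab = np.r_[["red"] * 40, ["half-red"] * 40]
        assert roc_auc(v, lab).raw == pytest.approx(
            roc_auc_score(lab == "red", v), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], ["red", "red"])


class TestAucCi:
    def test_disjoint_supports_degenerate_interval(self, rng):
        v = np.r_[rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)]
        lab = np.r_[["half-red"] * 30, ["red"] * 30]
        assert auc_ci(v, lab, B=200, seed=1) == (1.0, 1.0)

    def test_interval_contains_point_auc_small_n(self, rng):
        v = np.array([1.0, 2.0, 3.0, 2.5, 3.5, 1.5])
        lab = np.array(["half-red"] * 3 + ["red"] * 3)
        lo, hi = auc_ci(v, lab, B=500, seed=2)
        point = roc_auc(v, lab).auc
        assert lo <= point <= hi
        assert hi - lo > 0.1  # wide at n=3 per class

    def test_fixed_seed_reproducible(self, rng):
        v = rng.normal(size=40)
        lab = np.r_[["red"] * 20, ["half-red"] * 20]
        assert auc_ci(v, lab, B=300, seed=9) == auc_ci(v, lab, B=300, seed=9)


class TestTableSummary:
    def test_ten_sensor_features_in_ten_rows_out(self, enose_table):
        res = table_summary(enose_table, B=100)
        assert len(res) == 10
        assert (res["CI95_low"] <= res["AUC"] + 1e-12).all()
        assert (res["AUC"] <= res["CI95_high"] + 1e-12).all()
        assert (res["AUC"] >= 0.5).all()
        assert np.allclose(res["FC"] * res["FC_reciprocal"], 1.0)

    def test_empty_feature_set(self, enose_table):
        res = table_summary(enose_table, feature_cols=[])
        assert res.empty

    def test_disjoint_and_flat_sensors(self, enose_table):
        """Sensors with disjoint printed stage ranges saturate the battery
        (AUC = 1, FDR-significant); the near-identical S4/S10 do not."""
        res = table_summary(enose_table, B=100).set_index("feature")
        for s in ("S7", "S9"):
            assert res.loc[s, "AUC"] == 1.0
            assert res.loc[s, "fdr_significant"]
            assert res.loc[s, "p"] < 0.001
        for s in ("S4", "S10"):
            assert res.loc[s, "AUC"] < 0.95  # far from saturation

    def test_formatted_layout(self, enose_table):
        res = table_summary(enose_table, B=100)
        out = univariate.format_results_table(res)
        assert list(out.columns) == ["ID", "half-red", "red", "p", "FC", "AUC", "CI 95%"]
        assert out["half-red"].str.contains(r"\[").all()
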