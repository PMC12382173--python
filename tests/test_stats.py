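"""Statistical layer: Welch tests, ROC/Youden, ICC(2,k), linear models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from washmap.phantom import MeasureSpec, reference_cohort_spec, simulate_cohort
from washmap.stats import (
    binormal_auc,
    cohort_report,
    empirical_auc,
    fit_linear_model,
    icc2k,
    roc_analysis,
    truncated_normal_auc,
    welch_t,
)


def brute_force_auc(pos, neg):
    """Tie-aware pairwise enumeration oracle."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_icc2k(table):
    """ICC(2,k) from first-principles two-way ANOVA sums of squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    msr = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((table - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.ci95_diff[0] < 0.0 < res.ci95_diff[1]

    def test_group_summaries_match_hand_computation(self):
        res = welch_t((0.39, 0.21, 29), (0.23, 0.15, 53))
        assert res.t == pytest.approx(3.63, abs=0.005)
        assert res.df == pytest.approx(44.0, abs=0.05)
        assert res.p < 0.001

    def test_raw_equals_summary(self, rng):
        a = rng.normal(0.5, 1.2, 40)
        b = rng.normal(0.1, 0.8, 25)
        raw = welch_t(a, b)
        summ = welch_t((a.mean(), a.std(ddof=1), 40), (b.mean(), b.std(ddof=1), 25))
        assert raw.t == pytest.approx(summ.t, abs=1e-12)
        assert raw.df == pytest.approx(summ.df, abs=1e-12)

    def test_matches_scipy(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.4, 2, 50)
        res = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swap_antisymmetry(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        fwd, rev = welch_t(a, b), welch_t(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 2.0])


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3, positive_label="b")
        assert res.auc == 1.0
        assert res.youden_j == 1.0
        assert 3 < res.optimal_threshold < 10

    def test_low_positive_with_ties(self):
        # class A scores {0.3, 0.5}, class B {0.3, 0.2}, low values positive
        res = roc_analysis([0.3, 0.5, 0.3, 0.2], ["A", "A", "B", "B"],
                           positive_label="B", higher_is_positive=False)
        assert res.auc == pytest.approx(0.875)
        assert "<" in res.direction

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = np.array(["x"] * 2000 + ["y"] * 2000)
        res = roc_analysis(scores, labels, positive_label="y")
        assert res.auc == pytest.approx(0.5, abs=0.02)

    def test_matches_pair_enumeration_on_small_tables(self, rng):
        """Rank-based AUC equals the tie-aware pairwise oracle for all small tables."""
        for _ in range(200):
            m, n = rng.integers(1, 7, size=2)
            pos = rng.integers(0, 4, size=m).astype(float)
            neg = rng.integers(0, 4, size=n).astype(float)
            assert empirical_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=20),
           st.lists(st.floats(-5, 5), min_size=2, max_size=20))
    def test_complement_identity(self, pos, neg):
        pos, neg = np.asarray(pos), np.asarray(neg)
        assert empirical_auc(pos, neg) + empirical_auc(-pos, -neg) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = rng.choice(["p", "n"], size=100)
        if len(set(labels)) < 2:
            labels[:50] = "p"
            labels[50:] = "n"
        a1 = roc_analysis(scores, labels, positive_label="p").auc
        a2 = roc_analysis(np.exp(scores), labels, positive_label="p").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_youden_threshold_consistency(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 80)])
        labels = np.array(["pos"] * 60 + ["neg"] * 80)
        res = roc_analysis(scores, labels, positive_label="pos")
        sens = np.mean(scores[:60] > res.optimal_threshold)
        spec = np.mean(scores[60:] <= res.optimal_threshold)
        assert res.sensitivity_at_threshold == pytest.approx(sens)
        assert res.specificity_at_threshold == pytest.approx(spec)
        assert res.youden_j == pytest.approx(sens + spec - 1.0)
        assert res.ci95[0] <= res.auc <= res.ci95[1]

    def test_bootstrap_ci_is_seeded(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array(["p"] * 30 + ["n"] * 30)
        r1 = roc_analysis(scores, labels, "p", ci_method="bootstrap", seed=5)
        r2 = roc_analysis(scores, labels, "p", ci_method="bootstrap", seed=5)
        assert r1.ci95 == r2.ci95
        assert r1.ci95[0] <= r1.auc <= r1.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], ["a", "a"], positive_label="a")


class TestAnalyticAUC:
    def test_equal_means_give_half(self):
        assert binormal_auc(1.0, 0.5, 1.0, 0.7) == 0.5

    def test_group_summary_values(self):
        # wash-out ratio groups: Phi(0.16 / sqrt(0.21^2 + 0.15^2))
        assert binormal_auc(0.39, 0.21, 0.23, 0.15) == pytest.approx(0.732, abs=5e-4)
        # rCBV ratio groups: Phi(1.24 / sqrt(1.25^2 + 1.55^2))
        assert binormal_auc(3.49, 1.25, 2.25, 1.55) == pytest.approx(0.733, abs=5e-4)

    def test_truncated_normal_auc_reduces_to_binormal_without_truncation(self):
        hi = MeasureSpec(1.0, 0.4)
        lo = MeasureSpec(0.2, 0.6)
        assert truncated_normal_auc(hi, lo) == pytest.approx(
            binormal_auc(1.0, 0.4, 0.2, 0.6), abs=1e-6
        )

    def test_truncated_normal_auc_matches_simulation(self):
        hi = MeasureSpec(0.39, 0.21, 0.0, 1.0)
        lo = MeasureSpec(0.23, 0.15, 0.0, 1.0)
        rng = np.random.default_rng(0)
        x = hi.sample(100_000, rng)
        y = lo.sample(100_000, rng)
        assert truncated_normal_auc(hi, lo) == pytest.approx(empirical_auc(x, y), abs=0.005)


class TestICC:
    def test_worked_example(self):
        res = icc2k(np.array([[1, 2], [2, 3], [3, 4]], dtype=float))
        assert res.icc == pytest.approx(0.8, abs=1e-12)
        assert res.ms_rows == pytest.approx(2.0)
        assert res.ms_cols == pytest.approx(1.5)
        assert res.ms_error == pytest.approx(0.0, abs=1e-12)
        assert res.band == "good"

    def test_identical_raters_give_unity(self):
        ratings = np.column_stack([np.arange(6.0), np.arange(6.0)])
        res = icc2k(ratings)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_matches_brute_force_anova(self, rng):
        for _ in range(200):
            n = rng.integers(3, 15)
            k = rng.integers(2, 5)
            table = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * rng.uniform(0, 3)
            assert icc2k(table).icc == pytest.approx(brute_force_icc2k(table), abs=1e-10)

    def test_independent_ratings_near_zero(self, rng):
        table = rng.normal(size=(400, 2))
        assert abs(icc2k(table).icc) < 0.15

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        table = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2.0
        res = icc2k(table)
        df = pd.DataFrame(table, columns=["r1", "r2", "r3"])
        df["subject"] = np.arange(12)
        long = df.melt(id_vars="subject", var_name="rater", value_name="score")
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref = ref.set_index("Type")
        row = ref.loc["ICC(A,k)"] if "ICC(A,k)" in ref.index else ref.loc["ICC2k"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-8)
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=0.02)
        assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=0.02)

    @pytest.mark.parametrize("band,value", [
        ("poor", 0.3), ("moderate", 0.6), ("good", 0.8), ("excellent", 0.95),
    ])
    def test_koo_li_bands(self, band, value, rng):
        # large-n table whose ICC(2,k) sits mid-band: for k=2 raters with
        # subject variance lam^2 and error variance 1/2 per rater,
        # ICC(2,1) = lam^2/(lam^2 + 1/2) and ICC(2,k) = t requires
        # lam^2 = t / (4 (1 - t))
        subj = rng.normal(size=(2000, 1))
        lam = np.sqrt(value / (4.0 * (1.0 - value)))
        table = lam * subj + rng.normal(size=(2000, 2)) / np.sqrt(2)
        res = icc2k(table)
        assert res.icc == pytest.approx(value, abs=0.05)
        assert res.band == band

    def test_missing_cells_rejected(self):
        table = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            icc2k(table)


class TestLinearModel:
    def test_perfect_fit(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"y": x, "x": x})
        res = fit_linear_model(df, "y ~ x")
        assert res.coefficients.loc["x", "coef"] == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients.loc["Intercept", "coef"] == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_duplicated_predictor_rejected_with_names(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"y": rng.normal(size=30), "x1": x, "x2": x})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_model(df, "y ~ x1 + x2")

    def test_binary_outcome_coded_0_1(self):
        df = pd.DataFrame({
            "group": ["glioblastoma"] * 5 + ["metastasis"] * 5,
            "x": [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        })
        res = fit_linear_model(df, "group ~ x")
        assert res.outcome_coding == {"glioblastoma": 0, "metastasis": 1}

    def test_significant_markers_recovered_from_simulated_cohort(self):
        """Wash-out and rCBV coefficients are significant in most replicates.

        Monte-Carlo power at the reference group distributions (29 vs 53
        lesions) is ~0.87 for the wash-out ratio and ~0.73 for the rCBV
        ratio (500-replicate estimates); the bounds below allow for
        sampling noise at 100 replicates.
        """
        hits_wash = hits_rcbv = 0
        n_rep = 100
        for rep in range(n_rep):
            table = simulate_cohort(reference_cohort_spec(seed=1000 + rep))
            res = fit_linear_model(
                table,
                "group ~ washout_ratio + rcbv_ratio + adc_ratio + v_enhancing_mm3",
            )
            hits_wash += res.pvalue("washout_ratio") < 0.05
            hits_rcbv += res.pvalue("rcbv_ratio") < 0.05
        assert hits_wash / n_rep >= 0.75
        assert hits_rcbv / n_rep >= 0.6


class TestCohortReport:
    @pytest.fixture(scope="class")
    def table(self):
        return simulate_cohort(reference_cohort_spec(seed=42))

    def test_summaries_near_truth(self, table):
        report = cohort_report(table)
        row = report.summaries.query("measure == 'washout_ratio' and group == 'glioblastoma'").iloc[0]
        spec = reference_cohort_spec().groups[0].measures["washout_ratio"]
        assert row["mean"] == pytest.approx(spec.truncated_mean(), abs=3 * 0.21 / np.sqrt(29))
        assert row["n"] == 29

    def test_roc_rows_present_for_all_scores_and_subsets(self, table):
        report = cohort_report(table)
        assert set(report.roc_rows["score"]) == {"washout_ratio", "rcbv_ratio", "product"}
        assert set(report.roc_rows["subset"]) == {"all", "volume>=1cm3"}
        assert ((report.roc_rows["auc"] >= 0) & (report.roc_rows["auc"] <= 1)).all()

    def test_product_roc_equals_single_score_when_perfectly_correlated(self, rng):
        wash = np.concatenate([rng.normal(3, 1, 40), rng.normal(1, 1, 40)])
        wash = np.abs(wash) + 0.01
        df = pd.DataFrame({
            "group": ["glioblastoma"] * 40 + ["metastasis"] * 40,
            "washout_ratio": wash,
            "rcbv_ratio": 2.0 * wash,  # rank-identical -> product is monotone in wash
        })
        report = cohort_report(df, measures=("washout_ratio", "rcbv_ratio"))
        by_score = report.roc_rows.set_index(["score", "subset"])["auc"]
        assert by_score[("product", "all")] == pytest.approx(by_score[("washout_ratio", "all")])

    def test_single_lesion_group_reports_nan_sd(self):
        df = pd.DataFrame({
            "group": ["glioblastoma", "metastasis", "metastasis"],
            "washout_ratio": [0.5, 0.2, 0.3],
        })
        report = cohort_report(df, measures=("washout_ratio",), roc_scores=("washout_ratio",))
        row = report.summaries.query("group == 'glioblastoma'").iloc[0]
        assert np.isnan(row["sd"])

    def test_missing_group_rejected(self, table):
        with pytest.raises(ValueError):
            cohort_report(table[table["group"] == "metastasis"])

    def test_report_files_written(self, table, tmp_path):
        report = cohort_report(table, out_dir=tmp_path)
        assert (tmp_path / "summaries.csv").exists()
        assert (tmp_path / "roc.csv").exists()
        assert (tmp_path / "report.md").exists()
        assert report.figures and all((tmp_path / "boxplots.png").exists() for _ in report.figures)
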