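"""Statistical battery: oracles, identities, and degenerate inputs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from dwinode.stats import (
    SeparationError,
    binormal_auc,
    chi_square_test,
    compare_groups,
    delong_auc_variance,
    delong_compare,
    empirical_roc,
    fit_logistic,
    icc_agreement,
    mann_whitney,
    student_t,
    student_t_from_summaries,
)


class TestStudentT:
    def test_identical_summaries_give_zero(self):
        res = student_t_from_summaries(0.5, 0.1, 20, 0.5, 0.1, 30)
        assert res.statistic == 0.0 and res.p == 1.0 and res.df == 48

    def test_raw_and_summary_paths_agree(self, rng):
        x = rng.normal(0.0, 1.0, 23)
        y = rng.normal(0.3, 1.2, 45)
        a = student_t(x, y)
        b = student_t_from_summaries(x.mean(), x.std(ddof=1), 23, y.mean(), y.std(ddof=1), 45)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_matches_scipy_pooled(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 2, 25)
        res = student_t(x, y)
        want = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(want.statistic, abs=1e-12)
        assert res.p == pytest.approx(want.pvalue, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            student_t_from_summaries(0.5, 0.1, 1, 0.5, 0.1, 30)
        with pytest.raises(ValueError):
            student_t_from_summaries(0.5, 0.0, 10, 0.5, 0.1, 30)


class TestMannWhitney:
    def test_complete_separation_extremes(self):
        res = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.statistic < 0 and res.p < 0.05

    def test_swapping_samples_flips_z(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 18)
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)

    def test_all_tied_is_null(self):
        res = mann_whitney([2.0] * 5, [2.0] * 7)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_against_exact_enumeration(self):
        """Small-sample p agrees with exhaustive permutation of the
        group labels within 0.02."""
        x = np.array([1.2, 3.4, 2.2, 5.0])
        y = np.array([2.8, 6.1, 4.4, 7.0])
        res = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * len(y) / 2.0
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
            count += abs(u - mu) >= abs(u_obs - mu)
            total += 1
        assert res.p == pytest.approx(count / total, abs=0.02)

    def test_matches_scipy_asymptotic(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.4, 1, 30)
        res = mann_whitney(x, y)
        want = sps.mannwhitneyu(x, y, method="asymptotic")
        assert res.p == pytest.approx(want.pvalue, abs=1e-10)


class TestChiSquare:
    def test_identical_proportions_zero(self):
        res = chi_square_test([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_balanced_diagonal_two_by_two(self):
        assert chi_square_test([[10, 0], [0, 10]]).statistic == pytest.approx(20.0, abs=1e-12)

    def test_against_expected_counts_oracle(self):
        """Pearson statistic recomputed from first principles on the
        cohort sex table."""
        table = np.array([[12, 11], [31, 14]], dtype=float)
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        want = ((table - expected) ** 2 / expected).sum()
        res = chi_square_test(table.astype(int))
        assert res.statistic == pytest.approx(want, abs=1e-9)
        assert res.df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[5, 0], [9, 0]])


class TestROC:
    def test_perfect_separation(self):
        res = empirical_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], "higher")
        assert res.auc == 1.0 and res.youden == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_auc_equals_rank_statistic_identity(self, rng):
        """Trapezoidal AUC equals the midrank Mann-Whitney U / (n1*n2)
        on 50 random datasets including ties."""
        from sklearn.metrics import auc as sk_auc, roc_curve

        for _ in range(50):
            n1, n0 = rng.integers(5, 40, 2)
            pos = np.round(rng.normal(1.0, 1.0, n1), 1)  # rounding makes ties
            neg = np.round(rng.normal(0.0, 1.0, n0), 1)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones(n1), np.zeros(n0)]
            res = empirical_roc(scores, labels, "higher")
            u, _ = sps.mannwhitneyu(pos, neg)
            assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-12)
            fpr, tpr, _ = roc_curve(labels, scores)
            assert res.auc == pytest.approx(sk_auc(fpr, tpr), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_youden_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 30)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            return
        res = empirical_roc(scores, labels)
        assert res.youden == pytest.approx(res.sensitivity + res.specificity - 1.0, abs=1e-15)

    def test_tie_breaks_toward_higher_specificity(self):
        # Youden ties at (sens .5, spec 1) and (sens 1, spec .5)
        res = empirical_roc([2.0, 4.0, 1.0, 3.0], [1, 1, 0, 0], "higher")
        assert res.specificity == 1.0 and res.sensitivity == 0.5

    def test_lower_orientation_reports_original_units(self):
        # positives have LOWER scores (D-type parameters)
        res = empirical_roc([0.5, 0.6, 0.9, 1.0], [1, 1, 0, 0], "lower")
        assert res.auc == 1.0 and res.orientation == "lower"
        assert 0.5 <= res.cutoff <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1.0, 2.0], [1, 1])


class TestBinormal:
    def test_equal_means_give_half(self):
        assert binormal_auc(1.0, 0.2, 1.0, 0.5) == 0.5

    def test_monte_carlo_oracle(self, rng):
        """Closed form vs 10^6-draw simulation within 0.002."""
        mp, sp_, mn, sn = 0.782, 0.084, 0.688, 0.074
        want = binormal_auc(mp, sp_, mn, sn)
        pos = rng.normal(mp, sp_, 1_000_000)
        neg = rng.normal(mn, sn, 1_000_000)
        sim = (pos > neg).mean()
        assert sim == pytest.approx(want, abs=0.002)


class TestDeLong:
    def _data(self, rng, n1=30, n0=25, rho=0.7):
        latent = np.r_[rng.normal(1, 1, n1), rng.normal(0, 1, n0)]
        a = rho * latent + rng.normal(0, 1, n1 + n0)
        b = rho * latent + rng.normal(0, 1, n1 + n0)
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        return a, b, labels

    def test_identical_scores_give_p_one(self, rng):
        a, _, labels = self._data(rng)
        res = delong_compare(a, a.copy(), labels)
        assert res["z"] == 0.0 and res["p"] == 1.0

    def test_monotone_transform_invariance(self, rng):
        a, _, labels = self._data(rng)
        res = delong_compare(a, np.exp(a), labels)
        assert res["p"] == 1.0 and res["auc_a"] == pytest.approx(res["auc_b"], abs=1e-15)

    def test_variance_matches_structural_components_oracle(self, rng):
        """Single-AUC variance vs an explicit O(m*n) psi-matrix
        computation on a small case."""
        scores = np.array([0.1, 0.9, 0.4, 0.8, 0.35, 0.7, 0.2, 0.6])
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        m, n = len(pos), len(neg)
        psi = np.zeros((m, n))
        for i in range(m):
            for j in range(n):
                psi[i, j] = 1.0 if pos[i] > neg[j] else (0.5 if pos[i] == neg[j] else 0.0)
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        want = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
        assert delong_auc_variance(scores, labels) == pytest.approx(want, abs=1e-10)

    def test_direction_and_significance(self, rng):
        n1, n0 = 40, 40
        strong = np.r_[rng.normal(2, 1, n1), rng.normal(0, 1, n0)]
        weak = rng.normal(0, 1, n1 + n0)
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        res = delong_compare(strong, weak, labels)
        assert res["auc_a"] > res["auc_b"] and res["p"] < 0.05 and res["z"] > 0


class TestLogistic:
    def test_null_predictor_odds_ratio_near_one(self):
        rng = np.random.default_rng(0)
        n = 10_000
        cohort = pd.DataFrame(
            {
                "group": np.where(rng.random(n) < 0.5, "metastatic", "benign"),
                "adc": rng.normal(0.65, 0.06, n),
            }
        )
        fit = fit_logistic(cohort, ["adc"])
        assert 0.95 < fit.table.loc["adc", "odds_ratio"] < 1.05

    def test_binary_predictor_matches_cross_product_ratio(self):
        # 2x2 layout: outcome x exposure counts 30/10 vs 15/45
        rows = []
        for y, x, n in [(1, 1, 30), (1, 0, 10), (0, 1, 15), (0, 0, 45)]:
            rows += [{"group": "metastatic" if y else "benign", "xbin": float(x)}] * n
        cohort = pd.DataFrame(rows)
        fit = fit_logistic(cohort, ["xbin"])
        want = (30 * 45) / (10 * 15)
        assert fit.table.loc["xbin", "odds_ratio"] == pytest.approx(want, rel=1e-6)

    def test_perfect_separation_raises(self):
        cohort = pd.DataFrame(
            {
                "group": ["benign"] * 10 + ["metastatic"] * 10,
                "xsep": list(range(10)) + list(range(20, 30)),
            }
        )
        with pytest.raises(SeparationError):
            fit_logistic(cohort, ["xsep"])

    def test_forward_stepwise_prefers_stronger_predictor(self, rng):
        n = 400
        y = rng.random(n) < 0.5
        strong = y * 1.0 + rng.normal(0, 0.5, n)
        weak = rng.normal(0, 1.0, n)
        cohort = pd.DataFrame(
            {"group": np.where(y, "metastatic", "benign"), "strong": strong, "weak": weak}
        )
        fit = fit_logistic(cohort, ["weak", "strong"], selection="forward_stepwise")
        assert fit.selected[0] == "strong"


class TestICC:
    def test_duplicate_raters_give_one(self):
        x = np.tile(np.arange(1.0, 9.0)[:, None], (1, 2))
        res = icc_agreement(x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_rater_kills_agreement(self, rng):
        case = rng.normal(0, 1, 1000)
        x = np.column_stack([case, case + rng.normal(0, 10, 1000)])
        assert icc_agreement(x).icc < 0.05

    def test_matches_anova_table_oracle(self):
        """6x2 matrix vs a from-scratch mean-squares computation."""
        x = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [10, 6], [9, 1]], dtype=float)
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1)[:, None] - x.mean(0)[None, :] + grand) ** 2).sum() / (
            (n - 1) * (k - 1)
        )
        want = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_agreement(x).icc == pytest.approx(want, abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        case = rng.normal(10, 2, 40)
        x = np.column_stack([case + rng.normal(0, 0.5, 40), case + rng.normal(0.3, 0.5, 40)])
        res = icc_agreement(x)
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": np.tile(["a", "b"], 40),
                "ratings": x.ravel(),
            }
        )
        want = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="ratings")
        row = want[want["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci = row["CI95%"] if "CI95%" in want.columns else row["CI95"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(ci[0], abs=0.01)  # pingouin rounds the CI
        assert res.ci_high == pytest.approx(ci[1], abs=0.01)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement(np.full((8, 2), 3.0))


class TestCompareGroups:
    def test_normality_gate_switches_test(self, rng):
        n = 60
        normal = rng.normal(0, 1, 2 * n)
        skewed = rng.lognormal(0, 1.5, 2 * n)
        cohort = pd.DataFrame(
            {
                "group": ["benign"] * n + ["metastatic"] * n,
                "gauss": normal,
                "heavy": skewed,
            }
        )
        table = compare_groups(cohort, parameters=("gauss", "heavy"))
        assert table.loc["gauss", "test"] == "student_t"
        assert table.loc["heavy", "test"] == "mann_whitney"
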