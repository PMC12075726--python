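"""Group-comparison and diagnostic-performance statistics.

Implements the statistical battery used to separate benign from
metastatic nodes: normality-gated two-sample tests (pooled-variance
Student t or tie-corrected Mann-Whitney U), Pearson chi-square for
categorical tables, empirical ROC analysis with Youden-index cutoffs,
the closed-form binormal AUC used as a consistency check against
summary statistics, DeLong's structural-components comparison of
correlated AUCs, binary logistic regression (univariable and forward
stepwise multivariable) with odds ratios, and two-way absolute-
agreement intraclass correlation for observer reproducibility.

Conventions: the metastatic group is the positive class throughout;
parameters that are lower in metastatic nodes (the D-type diffusion
coefficients and CTRW alpha) are negated before ROC analysis so that
AUC >= 0.5, and the reported cutoff is mapped back to original units.
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
import statsmodels.api as sm

from .fitting import PARAMETER_NAMES

__all__ = [
    "METASTATIC_HIGHER",
    "TestResult",
    "ROCResult",
    "LogisticFit",
    "ICCResult",
    "SeparationError",
    "student_t_from_summaries",
    "student_t",
    "mann_whitney",
    "chi_square_test",
    "empirical_roc",
    "binormal_auc",
    "delong_compare",
    "delong_auc_variance",
    "fit_logistic",
    "icc_agreement",
    "compare_groups",
    "roc_table",
    "delong_matrix",
]

#: Parameters whose values run higher in metastatic nodes; the rest run
#: higher in benign nodes and are negated before ROC analysis.
METASTATIC_HIGHER = frozenset({"alpha_sem", "beta_froc", "mu_froc", "beta_ctrw", "miad_mm"})

#: Default odds-ratio scale: diffusion metrics are reported per 0.001
#: parameter units (coefficients per raw unit would be unreadably far
#: from 1), node size per mm.
OR_SCALE = {name: 1e-3 for name in PARAMETER_NAMES}


class SeparationError(RuntimeError):
    """Raised when logistic regression encounters complete separation."""


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    df: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.test not in ("student_t", "mann_whitney", "chi_square"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    orientation: str  # 'higher' or 'lower': score direction that calls positive
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    flavor: str
    model: str = "two-way random, absolute agreement, single measurement"

    def __post_init__(self):
        if self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


@dataclass(frozen=True)
class LogisticFit:
    """Coefficient table (index = predictor) with odds ratios per the
    recorded scale, Wald 95% CIs and p-values."""

    table: pd.DataFrame
    scale: dict
    selected: tuple
    converged: bool


# ---------------------------------------------------------------------------
# Two-sample and categorical tests


def student_t_from_summaries(mean1, sd1, n1, mean2, sd2, n2) -> TestResult:
    """Pooled-variance two-sample t from group summaries.

    The statistic is signed as (group1 - group2) with
    df = n1 + n2 - 2.  Pooled (Student) rather than Welch variance is
    used; on the published group summaries only the pooled form
    reproduces the printed t statistics.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least two observations")
    if min(sd1, sd2) <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("student_t", float(t), float(p), float(df))


def student_t(sample1, sample2) -> TestResult:
    """Pooled-variance t on raw samples (summaries computed internally)."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    return student_t_from_summaries(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def mann_whitney(sample1, sample2) -> TestResult:
    """Mann-Whitney U with midrank ties, tie-corrected normal
    approximation and continuity correction; two-sided p.

    The statistic reported is the Z score (signed so that sample1
    stochastically larger gives Z > 0); all-tied input yields Z = 0,
    p = 1.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return TestResult("mann_whitney", 0.0, 1.0)
    cc = min(0.5, abs(u1 - mu))  # continuity correction, toward the mean
    z = np.sign(u1 - mu) * (abs(u1 - mu) - cc) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("mann_whitney", float(z), float(min(p, 1.0)))


def chi_square_test(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on an r x c count table.

    Continuity correction is off by default (including 2x2); a zero row
    or column marginal is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(t, correction=yates)
    return TestResult("chi_square", float(res.statistic), float(res.pvalue), float(res.dof))


# ---------------------------------------------------------------------------
# ROC analysis


def _mann_whitney_auc(pos, neg) -> float:
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def empirical_roc(scores, labels, orientation: str = "auto") -> ROCResult:
    """Empirical ROC with the Youden-index operating point.

    ``labels`` are truthy for the positive (metastatic) class.
    ``orientation`` gives the score direction that indicates positivity:
    ``'higher'``, ``'lower'``, or ``'auto'`` (choose the direction with
    AUC >= 0.5).  Cutoffs are reported in original score units; ties in
    the Youden index break toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if orientation == "auto":
        orientation = "higher" if _mann_whitney_auc(s[y], s[~y]) >= 0.5 else "lower"
    if orientation not in ("higher", "lower"):
        raise ValueError("orientation must be 'higher', 'lower' or 'auto'")
    flip = -1.0 if orientation == "lower" else 1.0

    fpr, tpr, thr = roc_curve(y, flip * s)
    auc = _mann_whitney_auc(flip * s[y], flip * s[~y])
    youden = tpr - fpr
    idx = int(np.argmax(youden))  # fpr ascending -> first max = highest specificity
    cutoff = thr[idx]
    if not np.isfinite(cutoff):  # degenerate: best point is the (0, 0) corner
        idx = 1 if len(thr) > 1 else 0
        cutoff = thr[idx]
    sens = float(tpr[idx])
    spec = float(1.0 - fpr[idx])
    return ROCResult(
        auc=float(auc),
        cutoff=float(flip * cutoff),
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,  # identity holds exactly as reported
        orientation=orientation,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def binormal_auc(mean_pos, sd_pos, mean_neg, sd_neg) -> float:
    """Closed-form AUC of two normal score distributions:
    Phi(|mu_pos - mu_neg| / sqrt(sd_pos^2 + sd_neg^2)).

    Links published group mean/SD summaries to the empirical AUCs they
    imply, as a consistency oracle.
    """
    if min(sd_pos, sd_neg) <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf(abs(mean_pos - mean_neg) / np.hypot(sd_pos, sd_neg)))


# ---------------------------------------------------------------------------
# DeLong


def _delong_components(scores, labels):
    y = np.asarray(labels).astype(bool)
    pos = np.asarray(scores, dtype=float)[y]
    neg = np.asarray(scores, dtype=float)[~y]
    m, n = pos.size, neg.size
    # psi(X_i, Y_j) via midranks (Sun & Xu fast DeLong)
    all_r = sps.rankdata(np.concatenate([pos, neg]))
    pos_r = sps.rankdata(pos)
    neg_r = sps.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n  # per-positive structural components
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # per-negative
    auc = v10.mean()
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> float:
    """DeLong variance estimate of a single empirical AUC."""
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_compare(scores_a, scores_b, labels) -> dict:
    """DeLong test of two correlated AUCs measured on the same cases.

    Returns auc_a, auc_b, the 2x2 AUC covariance matrix, z and the
    two-sided p.  A zero-variance difference (e.g. identical or
    rank-equivalent scores) yields z = 0, p = 1 by convention.
    """
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-15:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = 2.0 * sps.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "cov": cov, "z": float(z), "p": float(p)}


# ---------------------------------------------------------------------------
# Logistic regression


def _wald_table(fit, names, scale) -> pd.DataFrame:
    coefs = fit.params[names]
    ses = fit.bse[names]
    rows = []
    for name in names:
        c, se = coefs[name], ses[name]
        rows.append(
            {
                "coef": c,
                "odds_ratio": np.exp(c),
                "or_ci_low": np.exp(c - 1.959963984540054 * se),
                "or_ci_high": np.exp(c + 1.959963984540054 * se),
                "p": float(fit.pvalues[name]),
                "scale": scale.get(name, 1.0),
            }
        )
    return pd.DataFrame(rows, index=names)


def _logit_fit(X: pd.DataFrame, y: np.ndarray):
    import warnings

    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=200, method="newton"
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise SeparationError(str(err)) from err
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(fit.params[X.columns]) > 25.0):
        # Newton diverging along a ridge: fitted probabilities saturate,
        # the hallmark of (quasi-)separation on standardized predictors.
        raise SeparationError("coefficients diverged; predictors separate the outcome")
    return fit


def fit_logistic(
    cohort: pd.DataFrame,
    predictors,
    outcome: str = "group",
    positive: str = "metastatic",
    selection: str = "none",
    scale: dict | None = None,
) -> LogisticFit:
    """Binary logistic regression of group membership.

    Predictors named among the nine diffusion parameters are rescaled
    to per-0.001 units before fitting (the recorded ``scale`` maps each
    predictor to the units of its odds ratio).  ``selection='forward_
    stepwise'`` grows the model greedily, admitting at each round the
    candidate with the smallest Wald p below 0.05.  Complete separation
    raises :class:`SeparationError` rather than returning a divergent
    fit.
    """
    predictors = list(predictors)
    scale = {**OR_SCALE, **(scale or {})}
    y = (cohort[outcome] == positive).to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValueError("outcome must contain both classes")
    X = pd.DataFrame(
        {p: cohort[p].to_numpy(dtype=float) / scale.get(p, 1.0) for p in predictors}
    )

    if selection == "none":
        fit = _logit_fit(X[predictors], y)
        return LogisticFit(_wald_table(fit, predictors, scale), scale, tuple(predictors), True)
    if selection != "forward_stepwise":
        raise ValueError("selection must be 'none' or 'forward_stepwise'")

    chosen: list = []
    while True:
        best = None
        for cand in predictors:
            if cand in chosen:
                continue
            try:
                fit = _logit_fit(X[chosen + [cand]], y)
            except SeparationError:
                continue
            p = float(fit.pvalues[cand])
            if p < 0.05 and (best is None or p < best[0]):
                best = (p, cand)
        if best is None:
            break
        chosen.append(best[1])
    if not chosen:
        raise ValueError("forward stepwise admitted no predictor at p < 0.05")
    fit = _logit_fit(X[chosen], y)
    return LogisticFit(_wald_table(fit, chosen, scale), scale, tuple(chosen), True)


# ---------------------------------------------------------------------------
# Intraclass correlation


def icc_agreement(measurements, flavor: str = "inter") -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, with the F-based 95% confidence interval.

    ``measurements`` is a case x rater matrix with no missing cells;
    ``flavor`` is a descriptor ('intra' for repeated measurements by
    one observer, 'inter' for different observers).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need at least 5 cases and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((x - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0):
        raise ValueError("ICC undefined for (near-)constant measurements")
    icc = (msr - mse) / denom

    # McGraw & Wong F-based CI for ICC(A,1)
    alpha = 0.05
    if mse == 0:
        lo = hi = 1.0
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1.0, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1.0)
        lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(float(icc), float(min(lo, icc)), float(max(hi, icc)), flavor)


# ---------------------------------------------------------------------------
# Cohort-level drivers


def compare_groups(
    cohort: pd.DataFrame,
    parameters=PARAMETER_NAMES,
    group_col: str = "group",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter benign-vs-metastatic comparison (summary table).

    Each parameter is Shapiro-Wilk tested in both groups; if either
    group departs from normality at ``normality_alpha`` the Mann-
    Whitney test is used, otherwise the pooled-variance t.  Rows carry
    group means/SDs, the statistic (t or Z, signed benign minus
    metastatic in the t convention) and the p-value.
    """
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError("cohort must contain exactly two groups")
    g1 = cohort[cohort[group_col] == "benign"]
    g2 = cohort[cohort[group_col] == "metastatic"]
    rows = []
    for name in parameters:
        x = g1[name].to_numpy(dtype=float)
        y = g2[name].to_numpy(dtype=float)
        normal = (
            sps.shapiro(x).pvalue > normality_alpha and sps.shapiro(y).pvalue > normality_alpha
        )
        res = student_t(x, y) if normal else mann_whitney(x, y)
        rows.append(
            {
                "parameter": name,
                "benign_mean": x.mean(),
                "benign_sd": x.std(ddof=1),
                "metastatic_mean": y.mean(),
                "metastatic_sd": y.std(ddof=1),
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def combined_model_scores(cohort: pd.DataFrame, predictors=("beta_ctrw", "miad_mm")) -> np.ndarray:
    """Predicted metastasis probability from a logistic model over the
    given predictors (the multiparametric 'combined model' score)."""
    fit = fit_logistic(cohort, list(predictors))
    y = (cohort["group"] == "metastatic").to_numpy(dtype=float)
    X = sm.add_constant(
        pd.DataFrame(
            {p: cohort[p].to_numpy(dtype=float) / fit.scale.get(p, 1.0) for p in predictors}
        ),
        has_constant="add",
    )
    full = sm.Logit(y, X).fit(disp=0)  # refit to recover the intercept
    lin = X.to_numpy() @ full.params.to_numpy()
    return 1.0 / (1.0 + np.exp(-lin))


def roc_table(cohort: pd.DataFrame, include_combined: bool = True) -> pd.DataFrame:
    """Diagnostic-performance table: one ROC row per diffusion
    parameter, node size (MiAD), and the combined logistic model."""
    y = cohort["group"] == "metastatic"
    rows = {}
    for name in list(PARAMETER_NAMES) + ["miad_mm"]:
        orient = "higher" if name in METASTATIC_HIGHER else "lower"
        rows[name] = empirical_roc(cohort[name].to_numpy(dtype=float), y, orient)
    if include_combined:
        rows["combined"] = empirical_roc(combined_model_scores(cohort), y, "higher")
    return pd.DataFrame(
        {
            name: {
                "auc": r.auc,
                "cutoff": r.cutoff,
                "youden": r.youden,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "orientation": r.orientation,
            }
            for name, r in rows.items()
        }
    ).T


def delong_matrix(cohort: pd.DataFrame, score_columns=None) -> pd.DataFrame:
    """Pairwise DeLong p-values between the per-parameter scores (and
    the combined model), after orienting every score metastatic-high."""
    y = cohort["group"] == "metastatic"
    scores = {}
    for name in score_columns or (list(PARAMETER_NAMES) + ["miad_mm"]):
        flip = 1.0 if name in METASTATIC_HIGHER else -1.0
        scores[name] = flip * cohort[name].to_numpy(dtype=float)
    scores["combined"] = combined_model_scores(cohort)
    names = list(scores)
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = delong_compare(scores[a], scores[b], y)["p"]
            out.loc[a, b] = out.loc[b, a] = p
    return out
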