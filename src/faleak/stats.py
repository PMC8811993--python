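"""Statistical toolkit for treatment-response prediction.

Group comparisons (pooled t, Pearson chi-square), ROC analysis with DeLong
structural-component inference, the binormal AUC closed form, two-way
random-effects absolute-agreement ICC, and backward stepwise logistic
regression with Wald elimination.  By convention the refractory group is
the positive class and higher scores predict refractoriness.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .types import RocComparison, SelectionTrace

__all__ = [
    "empirical_auc",
    "delong_variance_and_ci",
    "delong_paired_test",
    "binormal_auc",
    "mean_simulated_auc",
    "icc_agreement",
    "two_sample_t",
    "chi_square_2x2",
    "backward_stepwise_logistic",
    "roc_comparison",
]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return (y == classes.max()).astype(int)


def empirical_auc(scores, labels) -> float:
    """Mann-Whitney AUC (ties counted one-half); positive class = max label."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    return float(roc_auc_score(y, s))


def _structural_components(scores, labels):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64)
    x = s[y == 1]  # positives
    yneg = s[y == 0]
    psi = (x[:, None] > yneg[None, :]).astype(np.float64)
    psi += 0.5 * (x[:, None] == yneg[None, :])
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return auc, v10, v01


def delong_variance_and_ci(scores, labels):
    """AUC with its DeLong standard error and normal 95% CI (clipped to [0, 1]).

    Both classes must have at least two members so the component variances
    are defined.
    """
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("each class needs >= 2 members for a DeLong variance")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    se = float(np.sqrt(var))
    half = 1.959963984540054 * se
    ci = (float(max(0.0, auc - half)), float(min(1.0, auc + half)))
    return float(auc), se, ci


def delong_paired_test(scores_a, scores_b, labels):
    """Paired DeLong comparison of two predictors on the same subjects.

    Returns the z statistic for AUC(a) - AUC(b) and its two-sided p.
    Identical predictors give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired predictors must have equal length")
    auc_a, v10_a, v01_a = _structural_components(a, labels)
    auc_b, v10_b, v01_b = _structural_components(b, labels)
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:
        raise ValueError("each class needs >= 2 members")
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return float(z), min(p, 1.0)


def binormal_auc(mu_neg: float, sd_neg: float, mu_pos: float, sd_pos: float) -> float:
    """Closed-form AUC for two normal score distributions.

    Phi((mu_pos - mu_neg) / sqrt(sd_neg^2 + sd_pos^2)) — the probability
    that a random positive outscores a random negative.
    """
    if sd_neg <= 0 or sd_pos <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf((mu_pos - mu_neg) / np.hypot(sd_neg, sd_pos)))


def mean_simulated_auc(
    mu_neg: float, sd_neg: float, n_neg: int,
    mu_pos: float, sd_pos: float, n_pos: int,
    n_replicates: int = 10_000, seed: int | np.random.Generator | None = 0,
) -> float:
    """Mean Mann-Whitney AUC over replicate two-group normal cohorts.

    Vectorised: all replicate cohorts are ranked at once, so 10,000
    replicates of an 89-eye cohort take well under a second.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg = rng.normal(mu_neg, sd_neg, (n_replicates, n_neg))
    pos = rng.normal(mu_pos, sd_pos, (n_replicates, n_pos))
    both = np.concatenate([neg, pos], axis=1)
    ranks = sps.rankdata(both, axis=1)
    pos_rank_sum = ranks[:, n_neg:].sum(axis=1)
    auc = (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc.mean())


def icc_agreement(grader_a, grader_b) -> float:
    """Single-measure two-way random-effects absolute-agreement ICC, ICC(2,1).

    Computed from the two-way (subjects x raters) mean squares:
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) with k = 2 raters.
    Identical vectors give 1.0; raises on zero total variance.
    """
    a = np.asarray(grader_a, dtype=np.float64)
    b = np.asarray(grader_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("grader vectors must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need >= 3 subjects")
    data = np.stack([a, b], axis=1)  # n subjects x k raters
    k = 2
    grand = data.mean()
    if np.allclose(data, data.flat[0]):
        raise ValueError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate mean squares")
    return float((msr - mse) / denom)


def two_sample_t(x, y, *, welch: bool = False):
    """Two-sided independent-samples t test (Student's pooled by default)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def chi_square_2x2(table):
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity correction."""
    tab = np.asarray(table, dtype=np.float64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def _wald_or_table(fit, names) -> dict:
    out = {}
    ci = fit.conf_int()
    for name in names:
        beta = float(fit.params[name])
        lo, hi = float(ci.loc[name, 0]), float(ci.loc[name, 1])
        out[name] = {
            "coef": beta,
            "odds_ratio": float(np.exp(beta)),
            "or_ci95": (float(np.exp(lo)), float(np.exp(hi))),
            "p": float(fit.pvalues[name]),
        }
    return out


class _RidgeLogitFit:
    """Minimal results shim (params / pvalues / conf_int) for the ridge path."""

    def __init__(self, names, beta, cov):
        self.params = pd.Series(beta, index=names)
        se = np.sqrt(np.diag(cov))
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        self.pvalues = pd.Series(2 * sps.norm.sf(np.abs(z)), index=names)
        half = 1.959963984540054 * se
        self._ci = pd.DataFrame({0: beta - half, 1: beta + half}, index=names)

    def conf_int(self):
        return self._ci


def _ridge_logit(X: pd.DataFrame, y: np.ndarray, alpha: float) -> _RidgeLogitFit:
    """Newton-Raphson logistic fit with an L2 penalty (intercept unpenalised).

    Wald statistics use the inverse penalised Hessian — the standard ridge
    approximation that keeps separated fits finite.
    """
    Xd = sm.add_constant(X, has_constant="add")
    names = list(Xd.columns)
    A = Xd.to_numpy(dtype=float)
    pen = alpha * np.eye(A.shape[1])
    pen[0, 0] = 0.0  # do not shrink the intercept
    beta = np.zeros(A.shape[1])
    for _ in range(100):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = A.T @ (y - mu) - pen @ beta
        hess = A.T @ (A * w[:, None]) + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    eta = A @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    hess = A.T @ (A * (mu * (1 - mu))[:, None]) + pen
    cov = np.linalg.inv(hess)
    return _RidgeLogitFit(names, beta, cov)


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """ML logistic fit; returns (fit, separation_flag)."""
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=200)
        separated = (not fit.mle_retvals.get("converged", True)) or (
            np.abs(fit.params.to_numpy()).max() > 50
        ) or fit.pvalues.isna().any()
        if not separated:
            return fit, False
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError,
            ValueError):
        pass
    return _ridge_logit(X, np.asarray(y, dtype=float), alpha=1.0), True


def backward_stepwise_logistic(
    X: pd.DataFrame, y, p_stay: float = 0.05
) -> SelectionTrace:
    """Backward elimination of a logistic model by Wald p-values.

    Fits the full maximum-likelihood model, repeatedly removes the
    covariate with the largest Wald p above ``p_stay`` and refits, until
    every remaining covariate satisfies p <= ``p_stay`` (or none remain).
    The returned trace lists removals in order and, for the final model,
    each covariate's coefficient, odds ratio and Wald 95% CI for the odds
    ratio.  (Quasi-)separated fits fall back to a lightly ridge-penalised
    fit and set ``separation_flag``.
    """
    X = pd.DataFrame(X).copy()
    if X.isna().any().any():
        raise ValueError("covariates contain missing values")
    if X.shape[1] < 1:
        raise ValueError("need at least one covariate")
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        y = _check_labels(y)

    trace = SelectionTrace(p_stay=p_stay)
    step = 0
    current = list(X.columns)
    while current:
        fit, separated = _fit_logit(X[current], y)
        trace.separation_flag = trace.separation_flag or separated
        pvals = fit.pvalues.drop("const", errors="ignore")
        worst = pvals.idxmax()
        if pvals[worst] > p_stay and len(current) >= 1:
            step += 1
            trace.removed.append((step, str(worst), float(pvals[worst])))
            current.remove(worst)
            continue
        trace.final = _wald_or_table(fit, current)
        return trace
    trace.final = {}
    return trace


def roc_comparison(
    scores: pd.DataFrame | dict, labels, reference: str
) -> list[RocComparison]:
    """Per-predictor AUC/CI plus the paired DeLong contrast vs a reference.

    ``scores`` maps predictor name -> per-subject score (same subjects in
    every column).  The reference predictor's own row carries a ``None``
    p-value.
    """
    tab = pd.DataFrame(scores)
    if reference not in tab.columns:
        raise ValueError(f"reference predictor {reference!r} missing")
    out = []
    ref = tab[reference].to_numpy()
    for name in tab.columns:
        auc, _, ci = delong_variance_and_ci(tab[name], labels)
        if name == reference:
            p = None
        else:
            _, p = delong_paired_test(tab[name].to_numpy(), ref, labels)
        out.append(RocComparison(predictor_name=str(name), auc=auc, ci95=ci,
                                 delong_p_vs_reference=p, reference_name=reference))
    return out
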