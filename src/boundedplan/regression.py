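"""Per-subject regression of activity on information profiles, and the
group-level model comparison built on it.

The subject-level model is a non-negative multilinear regression

    activity(c) = alpha0 + alpha1 * f(I1(c)) + alpha2 * f(I2(c)) + noise

with link f in {identity, square, log(1+.), logistic sigmoid}, slopes
alpha1, alpha2 >= 0 (an activity increase per bit of processed
information) and a free intercept that absorbs baseline signal.  The fit
profiles the intercept out by centering and solves the remaining
non-negative least-squares problem.  On top of that sit: best-capacity
grid search, the nested F-test for the contribution of the planning
information I2, leave-one-out cross-validation, paired group statistics,
and the behavioral-prediction regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .links import LINKS


@dataclass
class RegressionFit:
    subject_id: str
    hypothesis: object
    beta1: float
    beta2: float
    link: str
    alpha0: float
    alpha1: float
    alpha2: float
    R2: float
    RSS: float
    F_nested: float = np.nan
    p_nested: float = np.nan
    loocv_mse: float | None = None
    exact_fit: bool = False


@dataclass
class GroupComparison:
    statistic_name: str
    effect_direction: str
    statistic_value: float
    p_value: float
    n_subjects: int
    correction: str = "none"
    corrected_alpha: float | None = None


@dataclass
class BehaviorCorrelation:
    slope: float
    intercept: float
    correlation: float
    p_value: float
    n_subjects: int
    shuffle_significant_fraction: float | None = None
    n_shuffles: int = 0


def design_matrix(profile, link):
    """(n_conditions, 2) design columns f(I1(c)), f(I2(c))."""
    f = LINKS[link]
    return np.column_stack([f(profile.I1_by_condition),
                            f(profile.I2_by_condition)])


def _nnls_with_intercept(X, y):
    """min ||a0 + X a - y||^2 with a >= 0, a0 free.

    The intercept is profiled out by centering; a centered column that is
    (numerically) constant cannot be identified jointly with the
    intercept, so its coefficient is pinned at 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    scale = np.abs(X).max(axis=0)
    keep = np.abs(Xc).max(axis=0) > 1e-12 * np.maximum(scale, 1.0)
    coef = np.zeros(X.shape[1])
    if not keep.all():
        warnings.warn("constant design column; coefficient pinned at 0",
                      RuntimeWarning, stacklevel=2)
    if keep.any():
        coef[keep], _ = optimize.nnls(Xc[:, keep], yc)
    alpha0 = ym - xm @ coef
    resid = y - alpha0 - X @ coef
    rss = float(resid @ resid)
    tss = float(yc @ yc)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return alpha0, coef, rss, max(min(r2, 1.0), 0.0)


def fit_information_regression(betas, profile, link="linear",
                               with_nested_f=True):
    """Fit one subject's condition betas against one information profile."""
    y = np.asarray(betas.betas, dtype=float)
    X = design_matrix(profile, link)
    if len(y) != X.shape[0]:
        raise ValueError("betas and profile have different condition counts")
    alpha0, coef, rss, r2 = _nnls_with_intercept(X, y)
    fit = RegressionFit(
        subject_id=betas.subject_id, hypothesis=profile.hypothesis,
        beta1=profile.beta1, beta2=profile.beta2, link=link,
        alpha0=float(alpha0), alpha1=float(coef[0]), alpha2=float(coef[1]),
        R2=r2, RSS=rss)
    if with_nested_f and len(y) > 3:
        fit.F_nested, fit.p_nested = nested_f_test(betas, profile, link)
        fit.exact_fit = rss <= 1e-24
    return fit


def nested_f_test(betas, profile, link="linear"):
    """Does I2 improve the fit beyond I1 alone?

    Classical nested-model F-statistic on ordinary least squares with an
    intercept: full model (1, f(I1), f(I2)) vs reduced (1, f(I1)), with
    (1, n - 3) degrees of freedom.  OLS (not the sign-constrained fit) is
    used here so the null distribution of the p-value is the textbook
    F(1, n-3): constraining alpha2 >= 0 would place half the null mass at
    p = 1 and destroy the calibration.
    """
    y = np.asarray(betas.betas, dtype=float)
    X = design_matrix(profile, link)
    n = len(y)
    if n <= 3:
        raise ValueError("nested F-test needs more than 3 conditions")

    def ols_rss(cols):
        A = np.column_stack([np.ones(n)] + cols)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        return float(r @ r)

    rss_full = ols_rss([X[:, 0], X[:, 1]])
    rss_red = ols_rss([X[:, 0]])
    df2 = n - 3
    if rss_full <= 1e-24:
        return np.inf, 0.0
    if rss_red <= rss_full + 1e-24 * max(rss_red, 1.0):
        return 0.0, 1.0
    F = (rss_red - rss_full) / (rss_full / df2)
    p = float(stats.f.sf(F, 1, df2))
    return float(F), p


def loocv(betas, profile, link="linear"):
    """Leave-one-condition-out mean squared prediction error."""
    y = np.asarray(betas.betas, dtype=float)
    X = design_matrix(profile, link)
    n = len(y)
    errs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        alpha0, coef, _, _ = _nnls_with_intercept(X[keep], y[keep])
        errs[i] = y[i] - alpha0 - X[i] @ coef
    return float((errs ** 2).mean())


@dataclass
class GridSearchResult:
    best: RegressionFit
    not_bounded: RegressionFit | None


def grid_search_fit(betas, grid, hypothesis, link="linear",
                    reference_point=(500.0, 500.0), skip_unconverged=True):
    """Best-R2 fit over the capacity grid, plus the max-capacity reference.

    Ties are broken toward larger beta1 + beta2, then larger beta2, so
    the search is deterministic on plateaus of the R2 landscape.
    """
    candidates = []
    for b1 in grid.beta1_values:
        for b2 in grid.beta2_values:
            profile = grid.get(hypothesis, b1, b2)
            if skip_unconverged and not profile.converged:
                continue
            fit = fit_information_regression(betas, profile, link)
            candidates.append(fit)
    if not candidates:
        raise ValueError("no (converged) grid points to search")
    best = max(candidates,
               key=lambda f: (f.R2, f.beta1 + f.beta2, f.beta2))
    not_bounded = None
    ref = (float(reference_point[0]), float(reference_point[1]))
    for f in candidates:
        if (f.beta1, f.beta2) == ref:
            not_bounded = f
            break
    return GridSearchResult(best=best, not_bounded=not_bounded)


def _paired_values(fits_a, fits_b, value):
    by_id_a = {f.subject_id: getattr(f, value) for f in fits_a}
    by_id_b = {f.subject_id: getattr(f, value) for f in fits_b}
    if set(by_id_a) != set(by_id_b):
        missing = set(by_id_a) ^ set(by_id_b)
        raise ValueError(f"unpaired subjects: {sorted(missing)}")
    ids = sorted(by_id_a)
    if len(ids) < 2:
        raise ValueError("need at least 2 paired subjects")
    return (np.array([by_id_a[i] for i in ids]),
            np.array([by_id_b[i] for i in ids]))


def compare_group(fits_a, fits_b, method="paired_rmANOVA", value="R2",
                  n_resamples=10_000, seed=0, bonferroni_divisor=None):
    """Paired group comparison of a fit statistic between two model
    families (A vs B), subject-matched by id.

    ``paired_rmANOVA`` is the two-level repeated-measures comparison,
    computed as the algebraically equivalent paired t-test;
    ``wilcoxon_signrank`` and the seeded one-sided sign-flip
    ``permutation_one_sided`` (tests A > B) are non-parametric
    alternatives.  A Bonferroni divisor, when given, is recorded together
    with the corrected significance threshold.
    """
    a, b = _paired_values(fits_a, fits_b, value)
    diff = a - b
    direction = "A>B" if diff.mean() > 0 else ("A<B" if diff.mean() < 0
                                               else "none")
    if method == "paired_rmANOVA":
        res = stats.ttest_rel(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon_signrank":
        if np.allclose(diff, 0):
            statistic, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(a, b)
            statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "permutation_one_sided":
        rng = np.random.default_rng(seed)
        observed = diff.mean()
        flips = rng.choice([-1.0, 1.0], size=(n_resamples, len(diff)))
        null = (flips * diff).mean(axis=1)
        p = float((np.sum(null >= observed) + 1) / (n_resamples + 1))
        statistic = float(observed)
    else:
        raise ValueError(f"unknown method {method!r}")
    comp = GroupComparison(
        statistic_name=method, effect_direction=direction,
        statistic_value=statistic, p_value=p, n_subjects=len(diff))
    if bonferroni_divisor:
        comp.correction = "bonferroni"
        comp.corrected_alpha = 0.05 / bonferroni_divisor
    return comp


def behavior_correlation(predicted_eu, error_rates, n_shuffles=0, seed=0,
                         alpha=0.05):
    """Regress observed performance (1 - error rate) on predicted E[U].

    The shuffle control re-runs the regression on randomly permuted
    subject pairings and reports the fraction of significant slopes,
    which calibrates the false-positive rate of the procedure.
    """
    eu = np.asarray(predicted_eu, dtype=float)
    perf = 1.0 - np.asarray(error_rates, dtype=float)
    if len(eu) != len(perf) or len(eu) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(eu) == 0 or np.ptp(perf) == 0:
        raise ValueError("zero variance in predicted or observed values")
    res = stats.linregress(eu, perf)
    out = BehaviorCorrelation(
        slope=float(res.slope), intercept=float(res.intercept),
        correlation=float(res.rvalue), p_value=float(res.pvalue),
        n_subjects=len(eu))
    if n_shuffles:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(len(perf))
            r = stats.linregress(eu, perf[perm])
            hits += r.pvalue < alpha
        out.shuffle_significant_fraction = hits / n_shuffles
        out.n_shuffles = n_shuffles
    return out


def fits_to_frame(fits):
    import pandas as pd
    rows = []
    for f in fits:
        d = dict(f.__dict__)
        hyp = d["hypothesis"]
        d["hypothesis"] = getattr(hyp, "value", str(hyp))
        rows.append(d)
    return pd.DataFrame(rows)
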