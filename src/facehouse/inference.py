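"""Statistical core: OLS, residual-based permutation inference, one-way
ANOVA with Tukey post hoc, and Bonferroni / Benjamini-Hochberg adjustments.

The permutation procedure tests one variable of interest in a linear model
without assuming normal errors (Freedman-Lane form).  A null model omitting
the variable is fitted; B surrogate outcomes are built as the null fitted
values plus a random permutation of the null residuals; the full model is
refitted to each surrogate, and the observed t is referred to the permuted
|t| distribution:

    p = (1 + #{|t_i| >= |t_orig|}) / (B + 1)

so p is bounded below by 1/(B+1) and the test is exact under
exchangeability of the null residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class FitResult:
    """OLS estimates for one linear model (original, un-permuted fit)."""

    params: pd.Series  # beta per predictor (outcome units / predictor unit)
    bse: pd.Series
    tvalues: pd.Series
    df_resid: int
    resid: np.ndarray
    fittedvalues: np.ndarray
    nobs: int
    _sm_result: object = field(default=None, repr=False)

    def summary(self):
        return self._sm_result.summary() if self._sm_result is not None else repr(self)


@dataclass
class PermutationResult:
    """Permuted t distribution and the resulting p value for one term."""

    variable: str
    t_orig: float
    t_perm: np.ndarray
    p_permuted: float
    n_perm: int
    seed: int


@dataclass
class AdjustedFamily:
    """A family of raw p values under one multiplicity adjustment."""

    raw: np.ndarray
    method: str  # "bonferroni_threshold" | "bh_fdr"
    m: int
    threshold: float | None = None  # per-test alpha for bonferroni_threshold
    adjusted: np.ndarray | None = None  # BH-adjusted p values
    significant: np.ndarray | None = None


def _design_frame(outcome, predictors, add_intercept=True):
    """Listwise-deleted (y, X DataFrame with intercept)."""
    y = pd.Series(np.asarray(outcome, dtype=float), name="outcome")
    X = pd.DataFrame(predictors).reset_index(drop=True).astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    return y.to_numpy(), X


def fit_ols(outcome, predictors, add_intercept: bool = True) -> FitResult:
    """Ordinary least squares of ``outcome`` on a predictor table.

    Missing values are removed listwise, so the residual degrees of freedom
    reflect the per-model available sample.
    """
    y, X = _design_frame(outcome, predictors, add_intercept)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("predictor matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    return FitResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        df_resid=int(res.df_resid),
        resid=np.asarray(res.resid),
        fittedvalues=np.asarray(res.fittedvalues),
        nobs=int(res.nobs),
        _sm_result=res,
    )


def _t_for_column(X: np.ndarray, Y: np.ndarray, j: int, pinv, cjj, df):
    """t statistics of column j for many outcome vectors at once."""
    B = Y @ pinv.T  # (n_sets, p)
    R = Y - B @ X.T
    s2 = (R * R).sum(axis=1) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        return B[:, j] / np.sqrt(s2 * cjj)


def residual_permutation_test(
    outcome,
    predictors,
    variable_of_interest: str,
    n_perm: int = 10_000,
    seed: int = 0,
    chunk: int = 2000,
) -> tuple:
    """Residual-based permutation test for one term of a linear model.

    Returns ``(FitResult, PermutationResult)``: the original full-model fit
    and the permutation p value for ``variable_of_interest``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    predictors = pd.DataFrame(predictors)
    if variable_of_interest not in predictors.columns:
        raise ValueError(f"{variable_of_interest!r} not among the predictors")

    full = fit_ols(outcome, predictors, add_intercept=True)
    t_orig = float(full.tvalues[variable_of_interest])

    # refit both models on the identical listwise-deleted sample
    y, X_full = _design_frame(outcome, predictors, add_intercept=True)
    X = X_full.to_numpy()
    j = list(X_full.columns).index(variable_of_interest)
    X0 = np.delete(X, j, axis=1)
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    fitted0 = X0 @ beta0
    resid0 = y - fitted0

    n, p = X.shape
    df = n - p
    pinv = np.linalg.pinv(X)
    cjj = float(np.linalg.inv(X.T @ X)[j, j])

    rng = np.random.default_rng(seed)
    t_perm = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.tile(np.arange(n), (b, 1))
        idx = rng.permuted(idx, axis=1)
        Y = fitted0[None, :] + resid0[idx]
        t_perm[done : done + b] = _t_for_column(X, Y, j, pinv, cjj, df)
        done += b

    exceed = int(np.sum(np.abs(t_perm) >= abs(t_orig)))
    p_perm = (1.0 + exceed) / (n_perm + 1.0)
    return full, PermutationResult(
        variable=variable_of_interest,
        t_orig=t_orig,
        t_perm=t_perm,
        p_permuted=p_perm,
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    tukey: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.F:.4g}, p = {self.p:.4g}",
            "Group means: "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.group_means.items()),
        ]
        if self.tukey is not None:
            lines.append(self.tukey.to_string(index=False))
        return "\n".join(lines)


def one_way_anova(groups: dict) -> AnovaResult:
    """Between-groups one-way ANOVA on a dict of name -> value array."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    arrays = {k: v[np.isfinite(v)] for k, v in arrays.items()}
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("each group needs at least 2 values")
    F, _ = stats.f_oneway(*arrays.values())
    F = max(float(F), 0.0)  # guard against negative rounding at F ~ 0
    n_total = sum(len(v) for v in arrays.values())
    df_b, df_w = len(arrays) - 1, n_total - len(arrays)
    return AnovaResult(
        F=F,
        df_between=df_b,
        df_within=df_w,
        p=float(stats.f.sf(F, df_b, df_w)),
        group_means={k: float(v.mean()) for k, v in arrays.items()},
    )


def tukey_hsd(groups: dict) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p).

    Returns one row per unordered pair with the mean difference and the
    adjusted p value.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    arrays = [a[np.isfinite(a)] for a in arrays]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for k in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[k],
                    "mean_diff": float(arrays[i].mean() - arrays[k].mean()),
                    "p_adj": float(res.pvalue[i, k]),
                }
            )
    return pd.DataFrame(rows)


def adjust_bonferroni(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def adjust_fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_family(pvalues, alpha: float = 0.05) -> AdjustedFamily:
    p = np.asarray(pvalues, dtype=float)
    thr = adjust_bonferroni(alpha, p.size)
    return AdjustedFamily(
        raw=p,
        method="bonferroni_threshold",
        m=p.size,
        threshold=thr,
        significant=p < thr,
    )


def bh_family(pvalues, alpha: float = 0.05) -> AdjustedFamily:
    p = np.asarray(pvalues, dtype=float)
    adj = adjust_fdr_bh(p)
    return AdjustedFamily(
        raw=p, method="bh_fdr", m=p.size, adjusted=adj, significant=adj < alpha
    )
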