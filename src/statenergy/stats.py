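"""Covariate-adjusted group statistics: ANCOVA routes, partial correlations.

Group comparisons of dynamics and energy measures are adjusted for age, sex
and education.  Normally distributed outcomes (Lilliefors-style KS test)
take a fixed-effects least-squares route (the design is purely
between-subject, so no random effects are identifiable); non-normal
outcomes take Quade's nonparametric ANCOVA (one-way ANOVA across groups on
the residuals of rank-transformed outcome regressed on rank-transformed
covariates).  Families of related tests are Bonferroni-corrected.  All
analyses are complete-case: missing cells (e.g. unvisited states) reduce n,
never get imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import InvalidParameterError

__all__ = [
    "GroupComparisonResult",
    "ks_normality",
    "compare_groups",
    "quade_ancova",
    "partial_correlation",
    "bonferroni",
]


@dataclass
class GroupComparisonResult:
    measure: str
    method: str                   # "linear" or "quade"
    F: float
    p_raw: float
    p_bonferroni: float
    contrast_beta: float          # CI-vs-CP (or configured contrast) from the linear fit
    contrast_ci95: tuple
    n_complete: int


def ks_normality(values) -> bool:
    """Lilliefors-style one-sample KS test for normality (alpha = 0.05).

    Tests against a normal with the sample's own mean and SD; returns True
    ("normal") when p > 0.05.  Constant input is reported non-normal with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise InvalidParameterError("need n >= 8 for the normality test")
    if np.ptp(x) == 0:
        warnings.warn("constant input: treated as non-normal", stacklevel=2)
        return False
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return bool(p > 0.05)


def _complete_frame(dv, group, covariates) -> pd.DataFrame:
    df = pd.DataFrame({"dv": np.asarray(dv, dtype=float),
                       "group": np.asarray(group, dtype=object)})
    cov_cols: list[str] = []
    if covariates is not None and len(getattr(covariates, "columns", [])) > 0:
        cov = covariates.reset_index(drop=True)
        for c in cov.columns:
            df[c] = cov[c].to_numpy(dtype=float)
            cov_cols.append(c)
    df = df.dropna()
    df.attrs["cov_cols"] = cov_cols
    return df


def quade_ancova(dv, group, covariates=None, measure: str = "",
                 family_size: int = 1) -> GroupComparisonResult:
    """Quade's rank-based ANCOVA.

    The outcome and each covariate are rank-transformed (midranks) over the
    full sample; the ranked outcome is regressed on the ranked covariates by
    least squares, and a one-way ANOVA F across groups is computed on the
    residuals.  With no covariates this reduces to a one-way ANOVA on
    ranks.  The contrast slot is not estimated on this route (NaN).
    """
    df = _complete_frame(dv, group, covariates)
    cov_cols = df.attrs["cov_cols"]
    _check_groups(df)
    y = sps.rankdata(df["dv"].to_numpy())
    if np.unique(y).size < 0.5 * y.size:
        warnings.warn("heavy ties in the outcome; midranks used", stacklevel=2)
    X = np.column_stack([np.ones(len(df))] +
                        [sps.rankdata(df[c].to_numpy()) for c in cov_cols])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    groups = [resid[(df["group"] == g).to_numpy()] for g in sorted(df["group"].unique())]
    F, p = sps.f_oneway(*groups)
    return GroupComparisonResult(
        measure=measure, method="quade", F=float(F), p_raw=float(p),
        p_bonferroni=float(min(1.0, family_size * p)),
        contrast_beta=float("nan"), contrast_ci95=(float("nan"), float("nan")),
        n_complete=len(df),
    )


def _check_groups(df: pd.DataFrame) -> None:
    counts = df["group"].value_counts()
    if (counts >= 3).sum() < 2:
        raise InvalidParameterError(
            "need >= 2 groups with >= 3 complete cases each")


def _linear_fit(df: pd.DataFrame, contrast: tuple[str, str]):
    cov_cols = df.attrs["cov_cols"]
    ref = contrast[1]
    if ref not in set(df["group"]):
        ref = sorted(df["group"].unique())[0]
    terms = [f"C(group, Treatment(reference='{ref}'))"] + cov_cols
    model = smf.ols("dv ~ " + " + ".join(terms), data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc[f"C(group, Treatment(reference='{ref}'))"]
    F, p = float(row["F"]), float(row["PR(>F)"])
    term = f"C(group, Treatment(reference='{ref}'))[T.{contrast[0]}]"
    if term in model.params.index:
        beta = float(model.params[term])
        lo, hi = model.conf_int().loc[term]
        ci = (float(lo), float(hi))
    else:                                     # contrast group absent
        beta, ci = float("nan"), (float("nan"), float("nan"))
    return F, p, beta, ci


def compare_groups(dv, group, covariates=None, force_method: str | None = None,
                   measure: str = "", family_size: int = 1,
                   contrast: tuple[str, str] = ("CI", "CP")) -> GroupComparisonResult:
    """Covariate-adjusted group comparison of one measure.

    Route selection follows the outcome's normality (KS) unless
    ``force_method`` is "linear" or "quade".  The CI-vs-CP contrast (beta
    and 95% CI, CP as reference) is always taken from the linear fit, which
    is also what the nonparametric route reports descriptively.
    ``family_size`` Bonferroni-corrects the group-effect p-value.
    """
    df = _complete_frame(dv, group, covariates)
    _check_groups(df)
    if force_method is None:
        try:
            method = "linear" if ks_normality(df["dv"]) else "quade"
        except InvalidParameterError:
            method = "linear"
    else:
        if force_method not in ("linear", "quade"):
            raise InvalidParameterError("force_method must be 'linear' or 'quade'")
        method = force_method
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        F_lin, p_lin, beta, ci = _linear_fit(df, contrast)
    if method == "linear":
        F, p = F_lin, p_lin
    else:
        cov = df[df.attrs["cov_cols"]] if df.attrs["cov_cols"] else None
        q = quade_ancova(df["dv"], df["group"], cov, measure=measure)
        F, p = q.F, q.p_raw
    return GroupComparisonResult(
        measure=measure, method=method, F=float(F), p_raw=float(p),
        p_bonferroni=float(min(1.0, family_size * p)),
        contrast_beta=beta, contrast_ci95=ci, n_complete=len(df),
    )


def partial_correlation(x, y, covariates=None):
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on the covariates (plus intercept) by
    least squares; the Pearson r of the residuals is tested with a t
    statistic on n - 2 - n_covariates degrees of freedom.  Complete-case.

    Returns ``(r, p, n)``; ``(nan, nan, n)`` when a residual variance is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((x.size, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[mask], y[mask], C[mask]
    n, n_cov = x.size, C.shape[1]
    if n <= n_cov + 2:
        raise InvalidParameterError("too few complete cases for the covariates")
    X = np.column_stack([np.ones(n), C])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if (rx.std() <= 1e-12 * max(x.std(), 1.0)
            or ry.std() <= 1e-12 * max(y.std(), 1.0)):
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - n_cov
    r_cl = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_cl * np.sqrt(df / (1.0 - r_cl**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p, n


def bonferroni(p_values, family_size: int | None = None):
    """Bonferroni adjustment: p_adj = min(1, m * p) with m the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise InvalidParameterError("family size must be >= 1")
    return np.minimum(1.0, m * p)
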