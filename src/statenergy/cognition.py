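"""Healthy-control-referenced cognitive scoring and impairment classification.

Raw scores on 7 cognitive domains are adjusted for age, sex and education
using linear models fitted in healthy controls (HC) only, residualised for
the whole cohort with the HC coefficients, and expressed as z-scores of the
HC residual distribution.  Patients are then labelled cognitively impaired
(CI: >= 2 of 7 domains Z < -2), mildly impaired (MCI: not CI but >= 2
domains Z < -1.5) or cognitively preserved (CP).  Both thresholds are
strict inequalities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "HCReferencedScorer",
    "adjust_and_zscore",
    "classify",
    "classify_table",
    "DOMAINS",
]

DOMAINS = (
    "executive_functioning",
    "verbal_memory",
    "processing_speed",
    "verbal_fluency",
    "visuospatial_memory",
    "working_memory",
    "attention",
)

COVARIATES = ("age", "sex", "education")


class HCReferencedScorer:
    """Fit per-domain covariate models on controls; z-score everyone.

    Per domain, a least-squares model ``score ~ 1 + age + sex + education``
    is fitted on the HC rows only.  ``transform`` residualises any cohort
    with those HC coefficients and z-scores the residuals with the HC
    residual mean and sample SD.  Covariates constant within HC are dropped
    with a warning (singular design).

    Parameters
    ----------
    domain_cols, covariate_cols : sequences of column names.
    """

    def __init__(self, domain_cols=DOMAINS, covariate_cols=COVARIATES):
        self.domain_cols = tuple(domain_cols)
        self.covariate_cols = tuple(covariate_cols)

    def get_params(self, deep: bool = True) -> dict:
        return {"domain_cols": self.domain_cols,
                "covariate_cols": self.covariate_cols}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in ("domain_cols", "covariate_cols"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, tuple(value))
        return self

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(df))]
        cols += [df[c].to_numpy(dtype=float) for c in self.used_covariates_]
        return np.column_stack(cols)

    def fit(self, hc_df: pd.DataFrame, y=None):
        if len(hc_df) < 3:
            raise InvalidParameterError("need >= 3 healthy-control subjects")
        missing = [c for c in (*self.domain_cols, *self.covariate_cols)
                   if c not in hc_df.columns]
        if missing:
            raise InvalidParameterError(f"missing columns: {missing}")
        if hc_df[list(self.covariate_cols)].isna().any().any():
            raise InvalidParameterError("covariates must be complete")
        used = []
        for c in self.covariate_cols:
            if hc_df[c].nunique() < 2:
                warnings.warn(f"covariate {c!r} is constant in HC; dropped",
                              stacklevel=2)
            else:
                used.append(c)
        self.used_covariates_ = tuple(used)
        X = self._design(hc_df)
        self.coef_ = {}
        self.resid_mean_ = {}
        self.resid_sd_ = {}
        for dom in self.domain_cols:
            y_dom = hc_df[dom].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(X, y_dom, rcond=None)
            resid = y_dom - X @ beta
            sd = resid.std(ddof=1)
            if sd == 0:
                raise InvalidParameterError(
                    f"HC residual SD is zero for domain {dom!r}")
            self.coef_[dom] = beta
            self.resid_mean_[dom] = float(resid.mean())
            self.resid_sd_[dom] = float(sd)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coef_"):
            raise InvalidParameterError("scorer is not fitted")
        X = self._design(df)
        out = {}
        for dom in self.domain_cols:
            resid = df[dom].to_numpy(dtype=float) - X @ self.coef_[dom]
            out[dom] = (resid - self.resid_mean_[dom]) / self.resid_sd_[dom]
        return pd.DataFrame(out, index=df.index)

    def fit_transform(self, hc_df: pd.DataFrame, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(hc_df).transform(df)


def adjust_and_zscore(scores: pd.DataFrame, covariates: pd.DataFrame,
                      hc_ids) -> pd.DataFrame:
    """HC-referenced z-scores for every subject (see ``HCReferencedScorer``).

    ``scores`` holds one column per domain, ``covariates`` the age/sex/
    education columns; both indexed by subject id.  ``hc_ids`` selects the
    reference rows.
    """
    df = scores.join(covariates)
    hc_ids = [s for s in hc_ids if s in df.index]
    scorer = HCReferencedScorer(domain_cols=tuple(scores.columns))
    return scorer.fit(df.loc[hc_ids]).transform(df)


def classify(z) -> str:
    """CP / MCI / CI label from 7 domain z-scores (strict thresholds).

    CI if >= 2 domains have Z < -2; else MCI if >= 2 domains have Z < -1.5;
    else CP.  Exactly -2.0 (or -1.5) does not count toward the threshold.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (7,):
        raise InvalidParameterError("expected exactly 7 domain z-scores")
    if np.any(np.isnan(z)):
        raise InvalidParameterError("missing domain z-score")
    if np.count_nonzero(z < -2.0) >= 2:
        return "CI"
    if np.count_nonzero(z < -1.5) >= 2:
        return "MCI"
    return "CP"


def classify_table(z_df: pd.DataFrame) -> pd.Series:
    """Apply ``classify`` row-wise; returns a subject-indexed label Series."""
    return pd.Series({idx: classify(row.to_numpy())
                      for idx, row in z_df.iterrows()}, name="group")
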