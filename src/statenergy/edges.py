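"""Edge (co-fluctuation) time series from regional BOLD signals.

Regional signals are z-scored over time (population SD) and multiplied
pointwise for every region pair, yielding one co-fluctuation series per
edge.  The temporal mean of an edge series is then *exactly* the Pearson
correlation of the two regions — edge time series are a temporal
unwrapping of static functional connectivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ContractViolationError, DegenerateInputError

__all__ = [
    "zscore_regional",
    "edge_time_series",
    "edge_pair_index",
    "reconstruct_frame",
    "EdgeTimeSeriesTransformer",
]

_ZSCORE_TOL = 1e-8


def _as_array(ts) -> np.ndarray:
    values = ts.to_numpy() if isinstance(ts, pd.DataFrame) else np.asarray(ts)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("time series must be a 2-D frames x regions array")
    if values.shape[0] < 2:
        raise ValueError("time series must contain at least 2 frames")
    if not np.all(np.isfinite(values)):
        raise ValueError("time series contains non-finite values")
    return values


def zscore_regional(ts):
    """Z-score each regional signal over time using population SD (ddof=0).

    The population-SD convention makes the edge-mean/Pearson identity exact.
    Accepts an ndarray or DataFrame (frames x regions); returns the same type.

    Raises
    ------
    DegenerateInputError
        If any region has zero temporal variance; the message names it.
    """
    values = _as_array(ts)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        if isinstance(ts, pd.DataFrame):
            names = ", ".join(str(ts.columns[i]) for i in zero[:5])
        else:
            names = ", ".join(str(i) for i in zero[:5])
        raise DegenerateInputError(
            f"region(s) with zero temporal variance cannot be z-scored: {names}"
        )
    z = (values - mean) / sd
    if isinstance(ts, pd.DataFrame):
        return pd.DataFrame(z, index=ts.index, columns=ts.columns)
    return z


def edge_pair_index(n_regions: int) -> list[tuple[int, int]]:
    """Ordered (i, j) pairs, i < j, row-major — the edge column order."""
    return [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]


def _check_zscored(z: np.ndarray) -> None:
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=0)
    if np.abs(mean).max() > _ZSCORE_TOL or np.abs(sd - 1.0).max() > _ZSCORE_TOL:
        raise ContractViolationError(
            "input is not z-scored (per-region mean 0 / population SD 1 required); "
            "run zscore_regional first"
        )


def edge_time_series(z):
    """Pointwise products of z-scored regional signals for every region pair.

    Parameters
    ----------
    z : ndarray or DataFrame, frames x regions
        Must already be z-scored (checked; violation raises
        ``ContractViolationError``).

    Returns
    -------
    values : ndarray, frames x n_edges  (n_edges = n (n-1) / 2)
    edge_index : list of (i, j) tuples, i < j, row-major order
    """
    values = _as_array(z)
    _check_zscored(values)
    n = values.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    edges = values[:, iu] * values[:, ju]
    return edges, list(zip(iu.tolist(), ju.tolist()))


def reconstruct_frame(edge_row: np.ndarray, n_regions: int, diagonal=None) -> np.ndarray:
    """Rebuild the symmetric n x n co-fluctuation matrix of one frame.

    The diagonal (z_i(t)^2, never stored) defaults to zero unless given.
    """
    edge_row = np.asarray(edge_row, dtype=float)
    mat = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    if edge_row.shape[0] != iu.size:
        raise ValueError("edge vector length does not match n_regions")
    mat[iu, ju] = edge_row
    mat[ju, iu] = edge_row
    if diagonal is not None:
        np.fill_diagonal(mat, diagonal)
    return mat


class EdgeTimeSeriesTransformer(TransformerMixin, BaseEstimator):
    """Transform frames x regions signals into frames x edges co-fluctuations.

    Parameters
    ----------
    zscore : bool, default True
        Z-score regions over time before taking products.  With ``False``
        the input must already be z-scored.

    Attributes
    ----------
    n_regions_ : int
    edge_index_ : list of (i, j) region-pair tuples, one per edge column.
    """

    def __init__(self, zscore: bool = True):
        self.zscore = zscore

    def fit(self, X, y=None):
        values = _as_array(X)
        self.n_regions_ = values.shape[1]
        self.edge_index_ = edge_pair_index(self.n_regions_)
        return self

    def transform(self, X):
        if not hasattr(self, "n_regions_"):
            self.fit(X)
        values = _as_array(X)
        if values.shape[1] != self.n_regions_:
            raise ValueError("region count differs from the fitted transformer")
        if self.zscore:
            values = zscore_regional(values)
        edges, _ = edge_time_series(values)
        return edges
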