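"""Connectivity-state identification by city-block k-means on pooled edge frames.

Frames of edge time series, pooled across subjects, are clustered with
k-means under the L1 (city-block) metric.  The L1-optimal centroid is the
componentwise *median* of the assigned frames, so Lloyd iterations here use
median updates — a mean update would not minimise L1 inertia.  The number of
states is chosen with an elbow rule on the inertia curve, and each state
centroid is described by graph metrics (strength, efficiency, modularity,
per-network eigenvector centrality) used to name the state after the
resting-state network with maximal centrality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numba
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.isotonic import IsotonicRegression

from .edges import reconstruct_frame
from .exceptions import DegenerateInputError, InvalidParameterError

__all__ = [
    "CityBlockKMeans",
    "StateSet",
    "StateDescriptors",
    "fit_states",
    "inertia_curve",
    "select_k_elbow",
    "describe_state",
    "match_states",
]

logger = logging.getLogger(__name__)


@numba.njit(fastmath=True, cache=True)
def _l1_distances_nb(X, centers):  # pragma: no cover - exercised via wrapper
    n, d = X.shape
    k = centers.shape[0]
    out = np.empty((n, k), dtype=X.dtype)
    for i in range(n):
        for j in range(k):
            acc = 0.0
            for f in range(d):
                acc += abs(X[i, f] - centers[j, f])
            out[i, j] = acc
    return out


def _l1_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """n x k matrix of city-block distances (single pass, no temporaries)."""
    centers = np.ascontiguousarray(centers, dtype=X.dtype)
    return _l1_distances_nb(np.ascontiguousarray(X), centers)


def _cluster_medians(XT: np.ndarray, labels: np.ndarray, k: int,
                     centers: np.ndarray) -> np.ndarray:
    """Componentwise medians per cluster, via one column reorder of X^T.

    ``XT`` is the (features x samples) C-contiguous transpose; partitioning
    contiguous per-cluster segments is far faster than median over the
    sample axis of the original layout.  Clusters with no members keep
    their previous centroid.
    """
    order = np.argsort(labels, kind="stable")
    XTo = np.take(XT, order, axis=1)
    bounds = np.searchsorted(labels[order], np.arange(k + 1))
    out = centers.copy()
    for j in range(k):
        lo, hi = bounds[j], bounds[j + 1]
        n = hi - lo
        if n == 0:
            continue
        seg = XTo[:, lo:hi].copy()
        m = n // 2
        if n % 2:
            out[j] = np.partition(seg, m, axis=1)[:, m]
        else:
            part = np.partition(seg, [m - 1, m], axis=1)
            out[j] = 0.5 * (part[:, m - 1] + part[:, m])
    return out


class CityBlockKMeans(ClusterMixin, BaseEstimator):
    """k-means under the city-block (L1) metric with median centroid updates.

    Lloyd iterations: assign each point to the nearest centroid by L1
    distance, then replace each centroid by the componentwise median of its
    members (the L1-optimal centroid).  ``n_replicates`` seeded restarts are
    run and the solution with minimal total L1 inertia is kept.  Empty
    clusters are re-seeded from the point farthest from its assigned
    centroid (logged).

    Parameters
    ----------
    n_clusters : int
    n_replicates : int, default 5
        Independent seeded initialisations (init = k distinct sample rows).
    max_iter : int, default 200
    random_state : int or None

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) ndarray of medians
    labels_ : (n_samples,) int ndarray, 0-based
    inertia_ : float, total within-cluster L1 distance (min over replicates)
    n_iter_ : int, Lloyd iterations of the winning replicate
    n_reseeds_ : int, empty-cluster re-seed events in the winning replicate
    """

    def __init__(self, n_clusters: int = 4, n_replicates: int = 5,
                 max_iter: int = 200, random_state=None):
        self.n_clusters = n_clusters
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.random_state = random_state

    def _init_centers(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Seeded k-means++-style init under the L1 metric.

        The first centre is a random sample row; each further centre is
        drawn with probability proportional to the L1 distance to the
        nearest chosen centre (uniform fallback on all-zero distances).
        """
        n = X.shape[0]
        k = self.n_clusters
        chosen = [int(rng.integers(n))]
        min_dist = np.abs(X - X[chosen[0]]).sum(axis=1).astype(float)
        for _ in range(1, k):
            total = min_dist.sum()
            if total > 0:
                probs = min_dist / total
                nxt = int(rng.choice(n, p=probs))
            else:
                remaining = np.setdiff1d(np.arange(n), chosen)
                nxt = int(rng.choice(remaining))
            chosen.append(nxt)
            np.minimum(min_dist, np.abs(X - X[nxt]).sum(axis=1), out=min_dist)
        return X[chosen].copy()

    def _run_once(self, X: np.ndarray, XT: np.ndarray, rng: np.random.Generator):
        n, _ = X.shape
        k = self.n_clusters
        centers = self._init_centers(X, rng)
        labels = np.full(n, -1, dtype=np.int64)
        n_reseeds = 0
        for it in range(1, self.max_iter + 1):
            dist = _l1_distances(X, centers)
            new_labels = dist.argmin(axis=1)
            point_dist = dist[np.arange(n), new_labels]
            # re-seed empty clusters from the farthest point
            for j in range(k):
                if not np.any(new_labels == j):
                    far = int(point_dist.argmax())
                    centers[j] = X[far]
                    new_labels[far] = j
                    point_dist[far] = 0.0
                    n_reseeds += 1
                    logger.warning("empty cluster %d re-seeded from farthest point", j)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centers = _cluster_medians(XT, labels, k, centers)
        dist = _l1_distances(X, centers)
        labels = dist.argmin(axis=1)
        inertia = float(dist[np.arange(n), labels].sum())
        return centers, labels, inertia, it, n_reseeds

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise InvalidParameterError("X must be 2-D (samples x features)")
        if self.n_clusters < 1:
            raise InvalidParameterError("n_clusters must be >= 1")
        if X.shape[0] < self.n_clusters:
            raise InvalidParameterError(
                f"n_clusters={self.n_clusters} exceeds the {X.shape[0]} samples"
            )
        rng = np.random.default_rng(self.random_state)
        X = np.ascontiguousarray(X)
        XT = np.ascontiguousarray(X.T)
        best = None
        for _ in range(max(1, self.n_replicates)):
            result = self._run_once(X, XT, rng)
            if best is None or result[2] < best[2]:
                best = result
        centers, labels, inertia, n_iter, n_reseeds = best
        self.cluster_centers_ = np.asarray(centers, dtype=float)
        self.labels_ = labels
        self.inertia_ = inertia
        self.n_iter_ = n_iter
        self.n_reseeds_ = n_reseeds
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X)
        dist = _l1_distances(X.astype(self.cluster_centers_.dtype, copy=False),
                             self.cluster_centers_.astype(X.dtype, copy=False)
                             if X.dtype != self.cluster_centers_.dtype
                             else self.cluster_centers_)
        return dist.argmin(axis=1)


@dataclass
class StateSet:
    """Clustering solution over pooled edge frames.

    ``assignments`` uses 1-based state ids (1..k); ``frame_provenance`` maps
    each pooled row back to ``(subject_id, frame_index)``.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia_by_k: dict = field(default_factory=dict)
    frame_provenance: list | None = None

    @property
    def inertia(self) -> float:
        return self.inertia_by_k[self.k]


def fit_states(pooled_edges, k: int, replicates: int = 5, seed=None,
               frame_provenance=None) -> StateSet:
    """Cluster pooled edge frames into ``k`` states (city-block k-means)."""
    pooled_edges = np.asarray(pooled_edges)
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    km = CityBlockKMeans(n_clusters=k, n_replicates=replicates,
                         random_state=seed).fit(pooled_edges)
    return StateSet(
        k=k,
        centroids=km.cluster_centers_,
        assignments=km.labels_ + 1,
        inertia_by_k={k: km.inertia_},
        frame_provenance=frame_provenance,
    )


def inertia_curve(pooled_edges, k_values=range(2, 8), replicates: int = 5,
                  seed=None, frame_provenance=None):
    """Fit every candidate k; return ({k: inertia}, {k: StateSet})."""
    rng = np.random.default_rng(seed)
    fits: dict[int, StateSet] = {}
    for k in k_values:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fits[k] = fit_states(pooled_edges, k, replicates=replicates,
                             seed=sub_seed, frame_provenance=frame_provenance)
    inertias = {k: s.inertia for k, s in fits.items()}
    for s in fits.values():
        s.inertia_by_k = dict(inertias)
    return inertias, fits


def select_k_elbow(inertia_by_k: dict) -> int:
    """Elbow rule: k with maximal perpendicular distance to the endpoint chord.

    The candidate inertia curve is joined by a straight line from
    ``(k_min, inertia)`` to ``(k_max, inertia)``; the interior k farthest
    (perpendicularly) from that chord is returned, ties broken toward
    smaller k.  A non-monotone curve is smoothed by decreasing isotonic
    regression first (with a warning); a flat/linear curve with no elbow
    returns the smallest interior k (with a warning).
    """
    if len(inertia_by_k) < 3:
        raise InvalidParameterError("need at least 3 candidate k values")
    ks = np.array(sorted(inertia_by_k))
    inertias = np.array([float(inertia_by_k[k]) for k in ks])
    if np.any(np.diff(inertias) > 0):
        warnings.warn("inertia curve is not non-increasing; smoothing with "
                      "isotonic regression", stacklevel=2)
        iso = IsotonicRegression(increasing=False)
        inertias = iso.fit_transform(ks.astype(float), inertias)
    x1, y1 = ks[0], inertias[0]
    x2, y2 = ks[-1], inertias[-1]
    denom = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * ks - (x2 - x1) * inertias + x2 * y1 - y2 * x1)
    dist = dist / denom if denom > 0 else dist
    interior = slice(1, len(ks) - 1)
    d_int = dist[interior]
    scale = max(abs(y1 - y2), 1.0)
    if d_int.max() <= 1e-12 * scale:
        warnings.warn("no elbow detected (linear inertia decline); returning "
                      "the smallest interior k", stacklevel=2)
        return int(ks[1])
    return int(ks[interior][int(np.argmax(d_int))])


@dataclass
class StateDescriptors:
    """Graph-metric description of one state centroid."""

    state_id: int
    global_mean_connectivity: float
    global_efficiency: float
    modularity: float
    centrality_by_network: dict
    name: str


def _global_efficiency(absW: np.ndarray) -> float:
    n = absW.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(absW > 0, 1.0 / absW, np.inf)
    np.fill_diagonal(lengths, 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _modularity_louvain(absW: np.ndarray, n_restarts: int = 10, seed: int = 0) -> float:
    g = nx.Graph()
    g.add_nodes_from(range(absW.shape[0]))
    iu, ju = np.nonzero(np.triu(absW, k=1))
    g.add_weighted_edges_from((int(i), int(j), float(absW[i, j]))
                              for i, j in zip(iu, ju))
    if g.number_of_edges() == 0:
        return 0.0
    best = -np.inf
    for s in range(n_restarts):  # ties keep the lowest seed (strict >)
        comms = nx.community.louvain_communities(g, weight="weight", seed=seed + s)
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best:
            best = q
    return float(best)


def describe_state(centroid, edge_index, network_labels, state_id: int = 0,
                   seed: int = 0) -> StateDescriptors:
    """Describe a state centroid with global and network-level graph metrics.

    Global mean connectivity is the signed mean of the centroid's edge
    values.  Efficiency, modularity and eigenvector centrality operate on
    the elementwise absolute value of the reconstructed matrix, since path
    lengths and centrality are undefined for signed weights.  The state is
    named after the network with the highest mean eigenvector centrality.
    """
    centroid = np.asarray(centroid, dtype=float)
    network_labels = list(network_labels)
    n = len(network_labels)
    if centroid.shape[0] != n * (n - 1) // 2:
        raise InvalidParameterError("centroid length does not match region count")
    if np.all(centroid == 0):
        raise DegenerateInputError("all-zero centroid: degenerate state")
    W = reconstruct_frame(centroid, n)
    absW = np.abs(W)

    gmc = float(centroid.mean())
    geff = _global_efficiency(absW)
    q = _modularity_louvain(absW, seed=seed)

    eigvals, eigvecs = np.linalg.eigh(absW)
    v = np.abs(eigvecs[:, -1])          # Perron vector of |W|, unit L2 norm
    cent = pd.Series(v, index=pd.Index(network_labels, name="network"))
    by_net = cent.groupby(level=0).mean().sort_index()
    return StateDescriptors(
        state_id=state_id,
        global_mean_connectivity=gmc,
        global_efficiency=geff,
        modularity=q,
        centrality_by_network=by_net.to_dict(),
        name=str(by_net.idxmax()),
    )


def match_states(centroids, reference_centroids) -> np.ndarray:
    """Optimal assignment of ``centroids`` onto ``reference_centroids``.

    Returns an integer array ``perm`` such that ``centroids[i]`` is matched
    to ``reference_centroids[perm[i]]``, maximising the summed Pearson
    correlation of matched pairs (Hungarian algorithm).
    """
    C = np.asarray(centroids, dtype=float)
    R = np.asarray(reference_centroids, dtype=float)
    if C.shape != R.shape:
        raise InvalidParameterError("centroid sets must share shape")
    k = C.shape[0]
    if k == 1:
        return np.array([0])
    Cz = C - C.mean(axis=1, keepdims=True)
    Rz = R - R.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(Cz, axis=1)
    rn = np.linalg.norm(Rz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Cz @ Rz.T) / np.outer(cn, rn)
    corr = np.nan_to_num(corr)
    _, perm = linear_sum_assignment(-corr)
    return perm
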