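"""Cluster the candidate pool, find roots, detect boundary samples, build lists.

This is the reduce-and-organize half of the framework: run once per
repetition, before the learning iterations start.

* roots: one prototype per cluster — the member nearest its k-means
  centroid, annotated first (cold start).
* boundary set B: samples with at least one of their ``n_neighbors``
  nearest other pool samples assigned to a different cluster.  Typically
  ``B`` is much smaller than the pool, which is the whole point of the
  reduction.
* ordered lists: per-cluster candidate lists sorted by increasing distance
  to the cluster root (RDBS walks boundary members only; RDS walks all
  members).
* edge list: cross-cluster boundary pairs sorted by increasing distance
  (consumed by the IBE strategy).

All distances are Euclidean; all ties break by ascending candidate index
(lexicographic for edges), so every structure is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .data import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """k-means partition of the candidate pool (pool-local indices)."""

    k: int
    assignment: np.ndarray           # (m,) cluster id per pool sample
    centroids: np.ndarray            # (k, d)
    members: dict = field(default_factory=dict)   # cluster id -> sorted index list
    roots: dict = field(default_factory=dict)     # cluster id -> pool index

    @property
    def nonempty_clusters(self) -> list[int]:
        return sorted(cid for cid, mem in self.members.items() if len(mem) > 0)


@dataclass
class BoundarySet:
    boundary_idx: np.ndarray  # sorted pool-local indices of B
    n_neighbors: int

    def __contains__(self, idx: int) -> bool:
        return bool(np.isin(idx, self.boundary_idx))


@dataclass
class OrderedLists:
    """Per-cluster candidate lists in increasing distance to the root."""

    lists: dict                      # cluster id -> list of pool indices
    dist_to_root: dict               # pool index -> distance

    def total(self) -> int:
        return sum(len(v) for v in self.lists.values())


@dataclass
class EdgeList:
    """Cross-cluster boundary pairs (a, b, distance), increasing distance."""

    edges: list  # of (a, b, dist) with a < b


def cluster_pool(pool_features: np.ndarray, k: int, seed: int, n_init: int = 10) -> ClusterModel:
    """k-means partition of the pool; deterministic given ``seed``.

    The framework default is ``k = 2 * nc`` so that the roots annotated in
    the first iteration are likely to cover every class.
    """
    X = np.asarray(pool_features, dtype=float)
    m = X.shape[0]
    if k < 1 or k > m:
        raise ConfigurationError(f"k must satisfy 1 <= k <= {m}, got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignment = km.fit_predict(X)
    members = {cid: sorted(np.flatnonzero(assignment == cid).tolist()) for cid in range(k)}
    n_empty = sum(1 for mem in members.values() if not mem)
    if n_empty:
        logger.warning("%d empty cluster(s) reported by k-means", n_empty)
    model = ClusterModel(k=k, assignment=assignment, centroids=km.cluster_centers_, members=members)
    return model


def find_roots(model: ClusterModel, pool_features: np.ndarray) -> dict[int, int]:
    """Root of each non-empty cluster: member nearest its centroid.

    Exact ties resolve to the lowest pool index.  Empty clusters get no
    root and are dropped from list building downstream.
    """
    X = np.asarray(pool_features, dtype=float)
    roots: dict[int, int] = {}
    for cid in range(model.k):
        mem = model.members.get(cid, [])
        if not mem:
            logger.warning("cluster %d empty: no root, dropped from lists", cid)
            continue
        d = np.linalg.norm(X[mem] - model.centroids[cid], axis=1)
        roots[cid] = mem[int(np.argmin(d))]  # argmin -> first (lowest index) on ties
    model.roots = roots
    return roots


def detect_boundary(model: ClusterModel, pool_features: np.ndarray, n_neighbors: int = 5) -> BoundarySet:
    """Samples with a cross-cluster neighbor among their n nearest others.

    Implements the defining rule exactly: neighbors of x are the other pool
    samples ordered by (Euclidean distance, index); x is a boundary sample
    iff at least one of the first ``n_neighbors`` lies in a different
    cluster.  Quadratic in pool size, which is fine at the pool sizes this
    step runs at (it runs once per repetition).
    """
    X = np.asarray(pool_features, dtype=float)
    m = X.shape[0]
    if not (1 <= n_neighbors < m):
        raise ConfigurationError(f"n_neighbors must satisfy 1 <= n < {m}, got {n_neighbors}")
    D = cdist(X, X)
    boundary = []
    idx = np.arange(m)
    for i in range(m):
        others = idx[idx != i]
        order = np.lexsort((others, D[i, others]))
        nearest = others[order[:n_neighbors]]
        if np.any(model.assignment[nearest] != model.assignment[i]):
            boundary.append(i)
    return BoundarySet(boundary_idx=np.asarray(boundary, dtype=int), n_neighbors=n_neighbors)


def build_ordered_lists(model: ClusterModel, pool_features: np.ndarray,
                        candidates=None) -> OrderedLists:
    """Per-cluster lists of candidates sorted by increasing distance to root.

    ``candidates`` restricts membership (pass the boundary set for RDBS;
    default: every pool sample, the RDS setting).  The root itself never
    appears in its own list.
    """
    X = np.asarray(pool_features, dtype=float)
    if not model.roots:
        find_roots(model, X)
    cand = set(range(X.shape[0])) if candidates is None else set(int(i) for i in np.asarray(candidates).ravel())
    lists: dict[int, list[int]] = {}
    dist_to_root: dict[int, float] = {}
    for cid, root in sorted(model.roots.items()):
        mem = [i for i in model.members[cid] if i in cand and i != root]
        d = {i: float(np.linalg.norm(X[i] - X[root])) for i in mem}
        mem.sort(key=lambda i: (d[i], i))
        lists[cid] = mem
        dist_to_root.update(d)
    return OrderedLists(lists=lists, dist_to_root=dist_to_root)


def build_edge_list(bset: BoundarySet, model: ClusterModel, pool_features: np.ndarray) -> EdgeList:
    """All cross-cluster boundary pairs, ascending distance, lexicographic ties."""
    X = np.asarray(pool_features, dtype=float)
    b = sorted(int(i) for i in bset.boundary_idx)
    edges = []
    for pos, a in enumerate(b):
        for c in b[pos + 1:]:
            if model.assignment[a] != model.assignment[c]:
                edges.append((a, c, float(np.linalg.norm(X[a] - X[c]))))
    edges.sort(key=lambda e: (e[2], e[0], e[1]))
    return EdgeList(edges=edges)
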