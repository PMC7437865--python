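"""Query strategies: Rand, Clu, IBE, RDS and RDBS behind one contract.

Every strategy consumes the structures prepared once per repetition
(cluster model, boundary set, ordered lists, edge list) and, given the
current classifier, emits the next batch of candidate indices for the
oracle.  Indices here are pool-local (positions within the candidate pool
Z2'); the learning loop maps them back to global dataset indices.

Consumption semantics: a *selected* sample is gone for good; a sample that
was walked but rejected (its predicted label agreed with its root's) stays
available and is re-walked in later iterations, when a stronger classifier
may judge it differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .clustering import BoundarySet, ClusterModel, EdgeList, OrderedLists, \
    build_edge_list, build_ordered_lists, detect_boundary
from .data import ContractViolationError

PredictFn = Callable[[int], object]  # pool index -> predicted class label


@dataclass
class SelectionBatch:
    """One batch of chosen candidates plus the classifier's suggestions."""

    chosen_idx: list = field(default_factory=list)
    suggested_labels: dict = field(default_factory=dict)
    exhausted: bool = False


def initial_selection(model: ClusterModel) -> SelectionBatch:
    """First-iteration batch: the root of every non-empty cluster.

    Roots are the cold-start annotations — no classifier exists yet, so
    ``suggested_labels`` is empty.
    """
    chosen = [model.roots[cid] for cid in sorted(model.roots)]
    return SelectionBatch(chosen_idx=chosen, suggested_labels={}, exhausted=False)


def select_random(pool: list[int], consumed: set, budget: int, rng: np.random.Generator) -> SelectionBatch:
    """Uniform sample without replacement from the unconsumed pool."""
    avail = [i for i in pool if i not in consumed]
    if not avail:
        return SelectionBatch(exhausted=True)
    take = min(budget, len(avail))
    chosen = [int(i) for i in rng.choice(len(avail), size=take, replace=False)]
    chosen = [avail[i] for i in chosen]
    return SelectionBatch(chosen_idx=chosen, exhausted=len(avail) == take)


def select_clu(model: ClusterModel, consumed: set, budget: int, rng: np.random.Generator) -> SelectionBatch:
    """One random unconsumed member per cluster, round-robin until budget."""
    remaining = {cid: [i for i in model.members[cid] if i not in consumed]
                 for cid in model.nonempty_clusters}
    chosen: list[int] = []
    while len(chosen) < budget:
        progressed = False
        for cid in sorted(remaining):
            if len(chosen) >= budget:
                break
            avail = remaining[cid]
            if not avail:
                continue
            pick = avail.pop(int(rng.integers(len(avail))))
            chosen.append(pick)
            progressed = True
        if not progressed:
            break
    exhausted = not any(remaining.values())
    return SelectionBatch(chosen_idx=chosen, exhausted=exhausted)


def select_ibe(edges: EdgeList, predict: PredictFn, consumed: set, budget: int) -> SelectionBatch:
    """Increasing Boundary Edges: scan cross-cluster boundary pairs by
    ascending distance, selecting pairs the classifier labels inconsistently.

    Close cross-cluster pairs are similar yet straddle a cluster border, so
    a disagreeing prediction marks them as maximally uncertain.  If the scan
    ends under budget (e.g. a constant classifier never disagrees), the
    shortest remaining unconsumed edges fill the batch regardless of
    disagreement.  If taking both endpoints of a pair would overshoot the
    budget, only the lower-index endpoint is taken.
    """
    if predict is None:
        raise ContractViolationError("IBE needs a trained classifier (iteration >= 2)")
    chosen: list[int] = []
    suggested: dict[int, object] = {}
    taken = consumed | set()

    def free(x: int) -> bool:
        return x not in taken and x not in chosen

    for a, b, _ in edges.edges:
        if len(chosen) >= budget:
            break
        if not (free(a) and free(b)):
            continue
        la, lb = predict(a), predict(b)
        suggested[a], suggested[b] = la, lb
        if la != lb:
            if len(chosen) + 2 <= budget:
                chosen.extend([a, b])
            else:
                chosen.append(min(a, b))
    if len(chosen) < budget:  # fallback: shortest unconsumed edges, no disagreement required
        for a, b, _ in edges.edges:
            for x in (a, b):
                if len(chosen) >= budget:
                    break
                if free(x):
                    chosen.append(x)
            if len(chosen) >= budget:
                break
    universe = {x for a, b, _ in edges.edges for x in (a, b)}
    exhausted = all(x in consumed or x in chosen for x in universe)
    return SelectionBatch(chosen_idx=chosen, suggested_labels={i: suggested[i] for i in chosen if i in suggested},
                          exhausted=exhausted)


def _walk_lists(lists: OrderedLists, predict: PredictFn, root_labels: Mapping[int, object],
                consumed: set, budget: int, fallback: bool) -> SelectionBatch:
    """Shared RDS/RDBS walk: round-robin over lists; within a list, walk
    unconsumed samples in ascending distance to the root and select the
    first whose predicted label disagrees with the root's oracle label;
    with no disagreement, optionally select the farthest sample instead."""
    if predict is None:
        raise ContractViolationError("root-distance strategies need a trained classifier (iteration >= 2)")
    chosen: list[int] = []
    suggested: dict[int, object] = {}
    cache: dict[int, object] = {}

    def predicted(i: int):
        if i not in cache:
            cache[i] = predict(i)
        return cache[i]

    while len(chosen) < budget:
        progressed = False
        for cid in sorted(lists.lists):
            if len(chosen) >= budget:
                break
            avail = [i for i in lists.lists[cid] if i not in consumed and i not in chosen]
            if not avail:
                continue
            pick = None
            for s in avail:
                if predicted(s) != root_labels[cid]:
                    pick = s
                    break
            if pick is None and fallback:
                pick = avail[-1]  # farthest-from-root fallback
            if pick is not None:
                chosen.append(pick)
                if pick in cache:
                    suggested[pick] = cache[pick]
                progressed = True
        if not progressed:
            break
    remaining = any(i not in consumed and i not in chosen
                    for lst in lists.lists.values() for i in lst)
    return SelectionBatch(chosen_idx=chosen, suggested_labels=suggested, exhausted=not remaining)


def select_rds(lists: OrderedLists, predict: PredictFn, root_labels: Mapping[int, object],
               consumed: set, budget: int, fallback: bool = True) -> SelectionBatch:
    """Root Distance-based Sampling over lists built from ALL pool samples."""
    return _walk_lists(lists, predict, root_labels, consumed, budget, fallback)


def select_rdbs(lists: OrderedLists, predict: PredictFn, root_labels: Mapping[int, object],
                consumed: set, budget: int, fallback: bool = True) -> SelectionBatch:
    """Root Distance based Boundary Sampling: the RDS walk restricted to
    boundary samples (the lists must have been built over B only)."""
    return _walk_lists(lists, predict, root_labels, consumed, budget, fallback)


class Strategy:
    """Stateful per-repetition wrapper around the selection operations.

    ``prepare`` builds (once) whatever structures the strategy needs;
    ``select`` emits the next batch; ``mark_consumed`` records batches the
    loop actually spent annotation budget on.
    """

    name: str = ""
    needs_classifier: bool = False
    #: cluster-based strategies annotate the roots in iteration 1; the
    #: Rand baseline has no clustering stage and draws its first batch
    #: uniformly like any other.
    cold_start_roots: bool = True

    def __init__(self) -> None:
        self.consumed: set[int] = set()
        self.root_labels: dict[int, object] = {}
        self.model: ClusterModel | None = None

    def prepare(self, model: ClusterModel, pool_features: np.ndarray,
                n_neighbors: int, rng: np.random.Generator) -> None:
        self.model = model
        self.pool_size = int(np.asarray(pool_features).shape[0])
        self.rng = rng

    def set_root_labels(self, root_labels: Mapping[int, object]) -> None:
        self.root_labels = dict(root_labels)

    def mark_consumed(self, indices) -> None:
        self.consumed.update(int(i) for i in indices)

    def select(self, budget: int, predict: PredictFn | None) -> SelectionBatch:  # pragma: no cover
        raise NotImplementedError


class RandomStrategy(Strategy):
    name = "rand"
    cold_start_roots = False

    def select(self, budget, predict):
        return select_random(list(range(self.pool_size)), self.consumed, budget, self.rng)


class CluStrategy(Strategy):
    name = "clu"

    def select(self, budget, predict):
        return select_clu(self.model, self.consumed, budget, self.rng)


class IbeStrategy(Strategy):
    name = "ibe"
    needs_classifier = True

    def prepare(self, model, pool_features, n_neighbors, rng):
        super().prepare(model, pool_features, n_neighbors, rng)
        self.bset: BoundarySet = detect_boundary(model, pool_features, n_neighbors)
        self.edges: EdgeList = build_edge_list(self.bset, model, pool_features)

    def select(self, budget, predict):
        return select_ibe(self.edges, predict, self.consumed, budget)


class RdsStrategy(Strategy):
    name = "rds"
    needs_classifier = True
    fallback = True

    def prepare(self, model, pool_features, n_neighbors, rng):
        super().prepare(model, pool_features, n_neighbors, rng)
        self.lists: OrderedLists = build_ordered_lists(model, pool_features)

    def select(self, budget, predict):
        return select_rds(self.lists, predict, self.root_labels, self.consumed, budget, self.fallback)


class RdbsStrategy(Strategy):
    name = "rdbs"
    needs_classifier = True
    fallback = True

    def prepare(self, model, pool_features, n_neighbors, rng):
        super().prepare(model, pool_features, n_neighbors, rng)
        self.bset: BoundarySet = detect_boundary(model, pool_features, n_neighbors)
        self.lists: OrderedLists = build_ordered_lists(model, pool_features, self.bset.boundary_idx)

    def select(self, budget, predict):
        return select_rdbs(self.lists, predict, self.root_labels, self.consumed, budget, self.fallback)


STRATEGIES: dict[str, type[Strategy]] = {
    cls.name: cls for cls in (RandomStrategy, CluStrategy, IbeStrategy, RdsStrategy, RdbsStrategy)
}


def make_strategy(name: str) -> Strategy:
    try:
        return STRATEGIES[name]()
    except KeyError:
        raise ValueError(f"unknown strategy {name!r}; choose from {sorted(STRATEGIES)}") from None
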