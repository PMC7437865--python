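"""Synthetic Gaussian-mixture datasets and hand-verifiable fixtures.

The generator emulates the structure the framework assumes: classes that
form clusters in feature space, with a single knob (``separation``, the
distance between adjacent class means in units of the shared unit standard
deviation) controlling how much the classes overlap.  It stands in for the
small tabular biological datasets the method targets (gene expression,
protein localization, leaf descriptors): a few hundred rows, a handful of
classes, numeric features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import BoundarySet, ClusterModel, EdgeList, OrderedLists
from .data import ConfigurationError, FeatureTable

#: Frozen benchmark used by the stochastic learning-curve properties:
#: 4 classes x 50 samples in 2-D at separation 3 (moderate overlap), ten
#: generator seeds.  Frozen so directional claims are stable across runs.
BENCHMARK = dict(nc=4, per_class=50, d=2, separation=3.0)
BENCHMARK_SEEDS = tuple(range(10))


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian-blob dataset specification."""

    nc: int = 4
    per_class: int = 50
    d: int = 2
    separation: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.nc < 2 or self.per_class < 2 or self.d < 1 or self.separation <= 0:
            raise ConfigurationError(f"invalid blob spec {self}")


def make_blobs(spec: BlobSpec) -> FeatureTable:
    """Isotropic unit-variance Gaussian blobs, one per class.

    Means sit on a circle (d = 2, or nc > d) with adjacent-mean chord equal
    to ``separation``; for d > 2 with nc <= d they sit on scaled coordinate
    axes at pairwise distance ``separation``.  d = 1 uses an evenly spaced
    line.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nc, d, sep = spec.nc, spec.d, spec.separation
    means = np.zeros((nc, d))
    if d == 1:
        means[:, 0] = sep * np.arange(nc)
    elif d >= 2 and nc > d:
        radius = sep / (2.0 * np.sin(np.pi / nc))
        ang = 2.0 * np.pi * np.arange(nc) / nc
        means[:, 0], means[:, 1] = radius * np.cos(ang), radius * np.sin(ang)
    elif d == 2:
        radius = sep / (2.0 * np.sin(np.pi / nc))
        ang = 2.0 * np.pi * np.arange(nc) / nc
        means[:, 0], means[:, 1] = radius * np.cos(ang), radius * np.sin(ang)
    else:  # d > 2, nc <= d: scaled axes, pairwise distance = separation exactly
        for c in range(nc):
            means[c, c] = sep / np.sqrt(2.0)
    X = np.vstack([means[c] + rng.standard_normal((spec.per_class, d)) for c in range(nc)])
    labels = np.repeat([f"C{c}" for c in range(nc)], spec.per_class)
    ids = [f"s{i:04d}" for i in range(X.shape[0])]
    return FeatureTable(sample_ids=ids, features=X, labels=labels,
                        class_names=[f"C{c}" for c in range(nc)])


def make_boundary_fixture():
    """Six-point 2-D fixture with every downstream structure hand-computed.

    Geometry (indices 0..5, labels A for the left group, B for the right)::

        0:(0,0)  1:(2,0)  2:(0,1)   |   3:(3,0)  4:(5,0)  5:(5,1)

    k = 2 means the optimal partition is {0,1,2} | {3,4,5} (verified by
    enumerating candidate partitions).  Hand-derived expectations:

    * centroids (2/3, 1/3) and (13/3, 1/3); roots 0 and 4.
    * boundary set at n_neighbors=1: {1, 3} (the two facing samples);
      at n_neighbors=3: all six points.
    * RDS lists (all members, ascending distance to root): {0: [2, 1],
      1: [5, 3]}; RDBS lists at n_neighbors=1: {0: [1], 1: [3]}.
    * edge list at n_neighbors=1: [(1, 3, 1.0)].

    Returns ``(table, model, boundary_by_n, rds_lists, rdbs_lists, edges)``
    where ``boundary_by_n`` maps n_neighbors to the expected BoundarySet.
    """
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 1.0],
                    [3.0, 0.0], [5.0, 0.0], [5.0, 1.0]])
    labels = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
    table = FeatureTable(sample_ids=list(range(6)), features=pts, labels=labels,
                         class_names=["A", "B"])
    assignment = np.array([0, 0, 0, 1, 1, 1])
    centroids = np.array([[2.0 / 3.0, 1.0 / 3.0], [13.0 / 3.0, 1.0 / 3.0]])
    model = ClusterModel(k=2, assignment=assignment, centroids=centroids,
                         members={0: [0, 1, 2], 1: [3, 4, 5]}, roots={0: 0, 1: 4})
    boundary_by_n = {
        1: BoundarySet(boundary_idx=np.array([1, 3]), n_neighbors=1),
        3: BoundarySet(boundary_idx=np.array([0, 1, 2, 3, 4, 5]), n_neighbors=3),
    }
    rds_lists = OrderedLists(
        lists={0: [2, 1], 1: [5, 3]},
        dist_to_root={2: 1.0, 1: 2.0, 5: 1.0, 3: 2.0},
    )
    rdbs_lists = OrderedLists(lists={0: [1], 1: [3]}, dist_to_root={1: 2.0, 3: 2.0})
    edges = EdgeList(edges=[(1, 3, 1.0)])
    return table, model, boundary_by_n, rds_lists, rdbs_lists, edges
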