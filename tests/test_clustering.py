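"""Clustering, roots, boundary detection and list building.

Boundary detection and both ordering operations are checked against
independent brute-force references (plain Python loops / naive sorts).
"""

import numpy as np
import pytest

from fassl import (ConfigurationError, build_edge_list, build_ordered_lists,
                   cluster_pool, detect_boundary, find_roots)
from fassl.clustering import ClusterModel

from conftest import random_pool


def brute_force_boundary(X, assignment, n_neighbors):
    """Quadratic reference: neighbors ordered by (distance, index)."""
    m = len(X)
    out = []
    for i in range(m):
        dists = sorted((float(np.linalg.norm(X[i] - X[j])), j)
                       for j in range(m) if j != i)
        if any(assignment[j] != assignment[i] for _, j in dists[:n_neighbors]):
            out.append(i)
    return out


class TestClusterPool:
    def test_perfectly_separated_pairs(self):
        X = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        model = cluster_pool(X, k=2, seed=0)
        groups = {frozenset(mem) for mem in model.members.values()}
        assert groups == {frozenset({0, 1}), frozenset({2, 3})}

    def test_recovers_well_separated_gaussians(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [20, 0], [0, 20]])
        X = np.vstack([c + rng.normal(size=(20, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 20)
        model = cluster_pool(X, k=3, seed=1)
        # agreement up to cluster relabeling
        agree = max(
            np.mean(perm[model.assignment] == truth)
            for perm in map(np.array, __import__("itertools").permutations(range(3)))
        )
        assert agree >= 0.95

    def test_k_larger_than_pool_is_an_error(self):
        with pytest.raises(ConfigurationError):
            cluster_pool(np.zeros((3, 2)), k=4, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        a = cluster_pool(X, 4, seed=9)
        b = cluster_pool(X, 4, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)


class TestFindRoots:
    def test_exact_tie_goes_to_lower_index(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        model = ClusterModel(k=1, assignment=np.zeros(2, int),
                             centroids=np.array([[1.0, 0.0]]), members={0: [0, 1]})
        assert find_roots(model, X) == {0: 0}

    def test_root_minimizes_distance_to_centroid(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        model = ClusterModel(k=1, assignment=np.zeros(3, int),
                             centroids=np.array([[2.0, 0.0]]), members={0: [0, 1, 2]})
        assert find_roots(model, X) == {0: 1}

    def test_singleton_cluster_is_its_own_root(self):
        X = np.array([[3.0, 3.0]])
        model = ClusterModel(k=1, assignment=np.zeros(1, int),
                             centroids=np.array([[0.0, 0.0]]), members={0: [0]})
        assert find_roots(model, X) == {0: 0}

    def test_empty_cluster_has_no_root(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        model = ClusterModel(k=2, assignment=np.zeros(2, int),
                             centroids=np.zeros((2, 2)), members={0: [0, 1], 1: []})
        assert 1 not in find_roots(model, X)


class TestDetectBoundary:
    def test_fixture_expectations(self, boundary_fixture):
        table, model, expected, *_ = boundary_fixture
        for n, exp in expected.items():
            got = detect_boundary(model, table.features, n)
            np.testing.assert_array_equal(got.boundary_idx, exp.boundary_idx)

    def test_single_cluster_has_no_boundary(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        model = ClusterModel(k=1, assignment=np.zeros(10, int),
                             centroids=X.mean(0, keepdims=True),
                             members={0: list(range(10))})
        assert detect_boundary(model, X, 3).boundary_idx.size == 0

    def test_far_clusters_empty_then_full(self):
        X = np.array([[0, 0], [0, 1], [5, 0], [5, 1]], dtype=float)
        model = ClusterModel(k=2, assignment=np.array([0, 0, 1, 1]),
                             centroids=np.array([[0, 0.5], [5, 0.5]]),
                             members={0: [0, 1], 1: [2, 3]})
        assert detect_boundary(model, X, 1).boundary_idx.size == 0
        np.testing.assert_array_equal(detect_boundary(model, X, 3).boundary_idx,
                                      [0, 1, 2, 3])

    def test_n_neighbors_domain(self):
        X = np.zeros((4, 2))
        model = ClusterModel(k=1, assignment=np.zeros(4, int), centroids=np.zeros((1, 2)),
                             members={0: [0, 1, 2, 3]})
        with pytest.raises(ConfigurationError):
            detect_boundary(model, X, 4)

    def test_matches_brute_force_on_random_pools(self):
        """Spot-check oracle equivalence (the full 200-pool sweep runs in
        the acceptance suite)."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            X, model = random_pool(rng)
            n = int(rng.integers(1, min(10, len(X) - 1) + 1))
            got = detect_boundary(model, X, n).boundary_idx.tolist()
            assert got == brute_force_boundary(X, model.assignment, n)

    def test_boundary_grows_with_n_neighbors(self):
        rng = np.random.default_rng(3)
        X, model = random_pool(rng, n_max=60)
        prev: set = set()
        for n in range(1, min(8, len(X) - 1)):
            cur = set(detect_boundary(model, X, n).boundary_idx.tolist())
            assert prev <= cur
            prev = cur


class TestOrderedLists:
    def test_fixture_lists_all_members(self, boundary_fixture):
        table, model, _, rds_lists, _, _ = boundary_fixture
        got = build_ordered_lists(model, table.features)
        assert got.lists == rds_lists.lists
        assert got.dist_to_root == pytest.approx(rds_lists.dist_to_root)

    def test_fixture_lists_boundary_only(self, boundary_fixture):
        table, model, expected, _, rdbs_lists, _ = boundary_fixture
        got = build_ordered_lists(model, table.features, expected[1].boundary_idx)
        assert got.lists == rdbs_lists.lists

    def test_sorted_ascending_with_index_tiebreak(self):
        X = np.array([[0.0, 0.0], [3.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        model = ClusterModel(k=1, assignment=np.zeros(5, int),
                             centroids=np.array([[0.0, 0.0]]),
                             members={0: [0, 1, 2, 3, 4]}, roots={0: 0})
        got = build_ordered_lists(model, X)
        # distances: 2->1, 3->1, 4->1, 1->3 ; equidistant block ordered by index
        assert got.lists == {0: [2, 3, 4, 1]}

    def test_roots_never_listed_and_counts_match(self, boundary_fixture):
        table, model, expected, *_ = boundary_fixture
        bset = expected[1]
        got = build_ordered_lists(model, table.features, bset.boundary_idx)
        listed = [i for lst in got.lists.values() for i in lst]
        assert set(listed).isdisjoint(model.roots.values())
        boundary_roots = set(bset.boundary_idx.tolist()) & set(model.roots.values())
        assert len(listed) == len(bset.boundary_idx) - len(boundary_roots)

    def test_matches_naive_sort_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            X, model = random_pool(rng, n_max=50)
            find_roots(model, X)
            got = build_ordered_lists(model, X)
            for cid, lst in got.lists.items():
                root = model.roots[cid]
                expect = sorted((i for i in model.members[cid] if i != root),
                                key=lambda i: (float(np.linalg.norm(X[i] - X[root])), i))
                assert lst == expect


class TestEdgeList:
    def test_fixture_edges(self, boundary_fixture):
        table, model, expected, _, _, edges = boundary_fixture
        got = build_edge_list(expected[1], model, table.features)
        assert got.edges == pytest.approx(edges.edges)

    def test_same_cluster_pairs_excluded(self, boundary_fixture):
        table, model, expected, *_ = boundary_fixture
        got = build_edge_list(expected[3], model, table.features)
        for a, b, _ in got.edges:
            assert model.assignment[a] != model.assignment[b]

    def test_equal_distances_order_lexicographically(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        model = ClusterModel(k=2, assignment=np.array([0, 1, 1, 0]),
                             centroids=np.zeros((2, 2)),
                             members={0: [0, 3], 1: [1, 2]})
        from fassl.clustering import BoundarySet
        bset = BoundarySet(boundary_idx=np.arange(4), n_neighbors=1)
        got = build_edge_list(bset, model, X)
        assert [(a, b) for a, b, _ in got.edges] == [(0, 1), (0, 2), (1, 3), (2, 3)]

    def test_matches_naive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(13)
        from fassl.clustering import BoundarySet
        for _ in range(25):
            X, model = random_pool(rng, n_max=40)
            b = np.sort(rng.choice(len(X), size=min(12, len(X)), replace=False))
            got = build_edge_list(BoundarySet(b, 1), model, X)
            expect = sorted(
                ((a, c, float(np.linalg.norm(X[a] - X[c])))
                 for i, a in enumerate(b) for c in b[i + 1:]
                 if model.assignment[a] != model.assignment[c]),
                key=lambda e: (e[2], e[0], e[1]))
            assert got.edges == expect
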