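import numpy as np
import pytest

from fassl import BlobSpec, make_blobs, make_boundary_fixture
from fassl.clustering import ClusterModel


@pytest.fixture(scope="session")
def boundary_fixture():
    """Six-point hand-computed fixture (table, model, boundaries, lists, edges)."""
    return make_boundary_fixture()


@pytest.fixture(scope="session")
def small_table():
    """2-class, well-separated blob table for quick loop runs."""
    return make_blobs(BlobSpec(nc=2, per_class=30, d=2, separation=6.0, seed=11))


@pytest.fixture(scope="session")
def benchmark_table():
    """One instance of the frozen 4-class benchmark."""
    return make_blobs(BlobSpec(nc=4, per_class=50, d=2, separation=3.0, seed=0))


def random_pool(rng, n_max=100, k_max=6, d=2):
    """Random 2-D pool with a random cluster assignment (not k-means) for
    oracle-equivalence testing of purely geometric operations."""
    m = int(rng.integers(5, n_max + 1))
    k = int(rng.integers(1, min(k_max, m) + 1))
    X = rng.normal(size=(m, d)) * rng.uniform(0.5, 3.0)
    assignment = rng.integers(0, k, size=m)
    members = {cid: sorted(np.flatnonzero(assignment == cid).tolist()) for cid in range(k)}
    centroids = np.zeros((k, d))
    for cid, mem in members.items():
        if mem:
            centroids[cid] = X[mem].mean(axis=0)
    model = ClusterModel(k=k, assignment=assignment, centroids=centroids, members=members)
    return X, model
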