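import numpy as np
import pytest

from treetop.ensemble import TreeEnsemble, TreeSample
from treetop.nodes import ReferenceNodeSet
from treetop.preprocess import CellMatrix


def make_ensemble_from_edges(edge_lists, k):
    """Build a TreeEnsemble from explicit per-tree edge lists (unit weights
    unless given); nodes are singleton partitions over a dummy matrix."""
    trees = []
    for edges in edge_lists:
        norm = []
        for e in edges:
            i, j = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            norm.append((min(i, j), max(i, j), w))
        trees.append(TreeSample(edges=sorted(norm), sampled_cell_indices=np.arange(k)))
    nodes = ReferenceNodeSet(
        node_cell_indices=np.arange(k),
        retained_indices=np.arange(k),
        assignment=np.arange(k),
    )
    return TreeEnsemble(trees=trees, nodes=nodes)


def random_tree_edges(k, rng):
    """Uniform random labelled tree on k nodes via a random attachment order."""
    perm = rng.permutation(k)
    edges = []
    for idx in range(1, k):
        parent = perm[rng.integers(idx)]
        child = perm[idx]
        edges.append((min(parent, child), max(parent, child), 1.0))
    return sorted(edges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_matrix(rng):
    """Two well-separated Gaussian blobs in 3-D."""
    a = rng.normal(size=(150, 3)) * 0.1
    b = rng.normal(size=(150, 3)) * 0.1 + 5.0
    values = np.vstack([a, b])
    labels = np.array(["a"] * 150 + ["b"] * 150)
    return CellMatrix(values=values, labels=labels)


@pytest.fixture(scope="session")
def shipped_table():
    from treetop.reference import ReferenceTable

    return ReferenceTable.shipped()


# keep hypothesis deterministic and free of on-disk artifacts in the repo
import tempfile

from hypothesis import configuration as _hyp_configuration
from hypothesis import settings as _hyp_settings

_hyp_configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))
_hyp_settings.register_profile("treetop", database=None, derandomize=True)
_hyp_settings.load_profile("treetop")
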