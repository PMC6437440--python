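import itertools

import numpy as np
import pytest

from treetop.ensemble import (
    build_ensemble,
    minimum_spanning_tree,
    prune_union_graph,
    sample_tree,
    union_graph,
)
from treetop.nodes import build_node_set
from treetop.preprocess import CellMatrix, DownsampleResult
from treetop.simulate import generate_geometry

from .conftest import make_ensemble_from_edges


def brute_force_mst_weight(dist):
    """Minimum spanning-tree weight by enumerating every (k-1)-edge subset."""
    k = dist.shape[0]
    all_edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
    best = np.inf
    for combo in itertools.combinations(all_edges, k - 1):
        parent = list(range(k))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        comp = k
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                comp -= 1
        if comp == 1:
            best = min(best, sum(dist[i, j] for i, j in combo))
    return best


class TestMST:
    def test_three_node_enumeration(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        edges = minimum_spanning_tree(d)
        assert [(i, j) for i, j, _ in edges] == [(0, 1), (0, 2)]
        assert sum(w for _, _, w in edges) == 3.0

    def test_collinear_points_form_path(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = np.abs(pts - pts.T)
        edges = minimum_spanning_tree(d)
        assert [(i, j) for i, j, _ in edges] == [(0, 1), (1, 2)]

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(100):
            k = int(rng.integers(4, 7))
            pts = rng.normal(size=(k, 2))
            d = np.abs(pts[:, None, :] - pts[None, :, :]).sum(-1)
            w = sum(e[2] for e in minimum_spanning_tree(d))
            assert w == pytest.approx(brute_force_mst_weight(d))

    def test_rejects_non_finite(self):
        d = np.array([[0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            minimum_spanning_tree(d)

    def test_is_spanning_tree(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(10, 3))
            d = np.abs(pts[:, None, :] - pts[None, :, :]).sum(-1)
            edges = minimum_spanning_tree(d)
            assert len(edges) == 9
            parent = list(range(10))

            def find(a):
                while parent[a] != a:
                    a = parent[a]
                return a

            for i, j, _ in edges:
                ri, rj = find(i), find(j)
                assert ri != rj  # acyclic
                parent[ri] = rj


def _node_set(n_cells, k, seed=0, d=2):
    rng = np.random.default_rng(seed)
    m = CellMatrix(values=rng.normal(size=(n_cells, d)))
    ds = DownsampleResult(
        kept=np.arange(n_cells), downsampled=np.arange(0), outliers=np.arange(0)
    )
    return m, build_node_set(m, ds, k=k, seed=seed)


class TestSampling:
    def test_singleton_partitions_sample_node_cells(self):
        m, ns = _node_set(8, 8)
        tree = sample_tree(m, ns, seed=3)
        assert sorted(tree.sampled_cell_indices.tolist()) == sorted(
            ns.node_cell_indices.tolist()
        )

    def test_same_seed_same_tree(self):
        m, ns = _node_set(100, 10)
        t1 = sample_tree(m, ns, seed=5)
        t2 = sample_tree(m, ns, seed=5)
        assert t1.edges == t2.edges
        assert np.array_equal(t1.sampled_cell_indices, t2.sampled_cell_indices)

    def test_uniform_within_partition(self):
        # partitions of size 2: each member drawn with frequency 1/2
        m, ns = _node_set(100, 10, seed=2)
        sizes = ns.partition_sizes
        target = int(np.argmax(sizes >= 2))
        members = ns.partition_members()[target]
        draws = [
            sample_tree(m, ns, seed=s).sampled_cell_indices[target] for s in range(2000)
        ]
        freq = np.mean(np.asarray(draws) == members[0])
        assert freq == pytest.approx(1 / len(members), abs=0.05)

    def test_ensemble_trees_are_trees(self):
        m, ns = _node_set(200, 15, seed=4)
        ens = build_ensemble(m, ns, n_trees=20, seed=9)
        assert ens.n == 20
        for tree in ens.trees:
            assert len(tree.edges) == 14
            # connectivity: union-find over edges
            parent = list(range(15))

            def find(a):
                while parent[a] != a:
                    a = parent[a]
                return a

            comp = 15
            for i, j, _ in tree.edges:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
                    comp -= 1
            assert comp == 1


class TestUnionGraph:
    def test_identical_trees_frequency_one(self):
        ens = make_ensemble_from_edges([[(0, 1), (1, 2)]] * 5, k=3)
        g = union_graph(ens)
        assert [(i, j) for i, j, _, _ in g.edges] == [(0, 1), (1, 2)]
        assert all(f == 1.0 for _, _, f, _ in g.edges)

    def test_shared_and_private_edges(self):
        ens = make_ensemble_from_edges(
            [[(0, 1), (1, 2), (2, 3)], [(0, 1), (1, 2), (1, 3)]], k=4
        )
        g = union_graph(ens)
        freqs = {(i, j): f for i, j, f, _ in g.edges}
        assert freqs[(0, 1)] == 1.0 and freqs[(1, 2)] == 1.0
        assert freqs[(2, 3)] == 0.5 and freqs[(1, 3)] == 0.5

    def test_frequencies_sum_to_edge_slots(self, rng):
        m, ns = _node_set(300, 12, seed=6)
        ens = build_ensemble(m, ns, n_trees=30, seed=1)
        g = union_graph(ens)
        total = sum(f for _, _, f, _ in g.edges) * ens.n
        assert total == pytest.approx(30 * 11)

    def test_circle_data_union_contains_cycle(self):
        circle = generate_geometry("circle", n_obs=500, d=2, seed=0)
        ds = DownsampleResult(
            kept=np.arange(500), downsampled=np.arange(0), outliers=np.arange(0)
        )
        ns = build_node_set(circle, ds, k=20, seed=0)
        ens = build_ensemble(circle, ns, n_trees=50, seed=0)
        g = union_graph(ens)
        # each individual tree is acyclic, but the superposition closes the loop
        assert len(g.edges) > g.k - 1


class TestPruning:
    def test_all_equal_frequencies_unchanged(self):
        ens = make_ensemble_from_edges([[(0, 1), (1, 2)]] * 3, k=3)
        g = union_graph(ens)
        assert prune_union_graph(g).edges == g.edges

    def test_minimum_frequency_bridge_retained(self):
        # edge (2,3) is the only route to node 3 but occurs in 1 of 2 trees
        ens = make_ensemble_from_edges(
            [[(0, 1), (1, 2), (2, 3)], [(0, 1), (0, 2), (2, 3)]], k=4
        )
        pruned = prune_union_graph(union_graph(ens))
        assert (2, 3) in {(i, j) for i, j, _, _ in pruned.edges}
        assert pruned.is_connected()

    def test_output_always_connected(self, rng):
        m, ns = _node_set(400, 18, seed=8)
        ens = build_ensemble(m, ns, n_trees=40, seed=2)
        pruned = prune_union_graph(union_graph(ens))
        assert pruned.is_connected()
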