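import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from treetop.scoring import (
    BRANCH_POINT_LABEL,
    ConsistencyMatrix,
    consistency_matrix,
    cut_tree_at_node,
    marker_anova,
    mean_tree_distance,
    normalized_mutual_information,
    raw_branching_score,
    score_all_nodes,
)

from .conftest import make_ensemble_from_edges, random_tree_edges


def closed_form_branch_score(edge_list, k, x):
    """Oracle for identical-tree ensembles: cutting at x yields fixed
    components; the score is the total size of the 3rd-largest and smaller
    components of at least two nodes (a singleton is not a branch)."""
    adj = {i: set() for i in range(k)}
    for i, j, *_ in edge_list:
        adj[i].add(j)
        adj[j].add(i)
    seen = {x}
    sizes = []
    for start in range(k):
        if start in seen:
            continue
        stack, comp = [start], 0
        seen.add(start)
        while stack:
            u = stack.pop()
            comp += 1
            for v in adj[u]:
                if v not in seen and v != x:
                    seen.add(v)
                    stack.append(v)
        sizes.append(comp)
    sizes = [s for s in sizes if s >= 2]
    sizes.sort(reverse=True)
    return float(sum(sizes[2:]))


class TestCutTree:
    def test_path_cut_interior(self):
        ens = make_ensemble_from_edges([[(0, 1), (1, 2)]], k=3)
        labels = cut_tree_at_node(ens.trees[0], 1)
        assert labels[1] == -1
        assert labels[0] != labels[2]

    def test_star_centre_isolates_leaves(self):
        ens = make_ensemble_from_edges([[(0, 1), (0, 2), (0, 3), (0, 4)]], k=5)
        labels = cut_tree_at_node(ens.trees[0], 0)
        assert len(set(labels[1:])) == 4  # one component per leaf

    def test_leaf_cut_leaves_single_component(self):
        ens = make_ensemble_from_edges([[(0, 1), (1, 2)]], k=3)
        labels = cut_tree_at_node(ens.trees[0], 0)
        assert labels[1] == labels[2] != -1


class TestConsistencyMatrix:
    def test_identical_trees_give_block_01_matrix(self):
        ens = make_ensemble_from_edges([[(0, 1), (1, 2), (1, 3), (3, 4)]] * 4, k=5)
        cm = consistency_matrix(ens, 1)
        assert set(np.unique(cm.B)) <= {0.0, 1.0}
        # components cutting at 1: {0}, {2}, {3,4}
        b = {tuple(sorted((a, c))): cm.B[list(cm.others).index(a), list(cm.others).index(c)]
             for a in cm.others for c in cm.others if a < c}
        assert b[(3, 4)] == 1.0
        assert b[(0, 2)] == 0.0 and b[(0, 3)] == 0.0

    def test_two_tree_hand_enumeration(self):
        # tree1: a-x-b-c (a=0, x=1, b=2, c=3); cut at x: {a}, {b,c}
        # tree2: b-x-a-c; cut at x: {b}, {a,c}
        ens = make_ensemble_from_edges(
            [[(0, 1), (1, 2), (2, 3)], [(2, 1), (1, 0), (0, 3)]], k=4
        )
        cm = consistency_matrix(ens, 1)
        idx = {n: i for i, n in enumerate(cm.others)}
        assert cm.B[idx[0], idx[2]] == 0.0  # a,b never together
        assert cm.B[idx[0], idx[3]] == 0.5  # a,c together in tree2 only

    def test_entries_are_multiples_of_one_over_n(self, rng):
        ens = make_ensemble_from_edges(
            [random_tree_edges(8, rng) for _ in range(7)], k=8
        )
        cm = consistency_matrix(ens, 3)
        assert np.allclose(cm.B * 7, np.round(cm.B * 7))
        assert np.allclose(cm.B, cm.B.T)
        assert np.allclose(np.diag(cm.B), 1.0)


def block_matrix(sizes):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return (labels[:, None] == labels[None, :]).astype(float)


class TestRawScore:
    def test_two_block_matrix_scores_zero(self):
        cm = ConsistencyMatrix(node_x=0, others=np.arange(1, 17), B=block_matrix([10, 6]))
        score, _, branches = raw_branching_score(cm)
        assert score == 0.0
        assert len(set(branches)) == 2

    def test_three_block_matrix_scores_third_size(self):
        cm = ConsistencyMatrix(node_x=0, others=np.arange(1, 21), B=block_matrix([10, 6, 4]))
        score, _, branches = raw_branching_score(cm)
        assert score == pytest.approx(4.0)
        assert sorted(np.bincount(branches).tolist(), reverse=True) == [10, 6, 4]

    def test_five_block_multifurcation(self):
        cm = ConsistencyMatrix(
            node_x=0, others=np.arange(1, 24), B=block_matrix([8, 6, 4, 3, 2])
        )
        score, _, _ = raw_branching_score(cm)
        assert score == pytest.approx(4 + 3 + 2)

    def test_fewer_than_three_nodes_scores_zero(self):
        cm = ConsistencyMatrix(node_x=0, others=np.array([1, 2]), B=np.eye(2))
        score, _, branches = raw_branching_score(cm)
        assert score == 0.0

    def test_rejects_boundary_thresholds(self):
        cm = ConsistencyMatrix(node_x=0, others=np.arange(1, 5), B=np.eye(4))
        with pytest.raises(ValueError):
            raw_branching_score(cm, thresholds=np.array([0.0, 0.5]))

    def test_merging_branches_never_raises_score(self):
        # raising off-block similarity toward 1 merges branches and destroys branching
        prev = np.inf
        for off in (0.0, 0.2, 0.4, 0.6, 0.8):
            b = block_matrix([6, 5, 4])
            b[b == 0] = off
            cm = ConsistencyMatrix(node_x=0, others=np.arange(1, 16), B=b)
            score, _, _ = raw_branching_score(cm)
            assert score <= prev + 1e-9
            prev = score

    def test_score_bounded_by_k_minus_3(self, rng):
        ens = make_ensemble_from_edges(
            [random_tree_edges(10, rng) for _ in range(15)], k=10
        )
        res = score_all_nodes(ens)
        assert np.all(res.raw_scores <= 10 - 3 + 1e-9)


class TestScoreAllNodes:
    def test_path_trees_score_zero_everywhere(self):
        path = [[(i, i + 1) for i in range(9)]] * 5
        res = score_all_nodes(make_ensemble_from_edges(path, k=10))
        assert np.allclose(res.raw_scores, 0.0)

    def test_three_armed_star_centre_wins(self):
        # centre node 0; arms of 10, 6, 4 path nodes
        edges = []
        arms = [list(range(1, 11)), list(range(11, 17)), list(range(17, 21))]
        for arm in arms:
            edges.append((0, arm[0]))
            edges += [(arm[i], arm[i + 1]) for i in range(len(arm) - 1)]
        ens = make_ensemble_from_edges([edges] * 4, k=21)
        res = score_all_nodes(ens)
        assert res.branch_node == 0
        assert res.raw_scores[0] == pytest.approx(4.0)
        assert np.all(res.raw_scores[1:] < 4.0)
        assert res.n_branches == 3
        # branch point's own label marks its cells
        assert res.node_branches[0] == BRANCH_POINT_LABEL

    def test_identical_tree_oracle_equality(self, rng):
        """Deterministic ensembles: score equals the closed-form component sum."""
        for trial in range(100):
            k = int(rng.integers(5, 13))
            edges = random_tree_edges(k, rng)
            ens = make_ensemble_from_edges([edges] * 3, k=k)
            res = score_all_nodes(ens)
            for x in range(k):
                assert res.raw_scores[x] == pytest.approx(
                    closed_form_branch_score(edges, k, x)
                ), f"trial {trial}, node {x}"

    def test_argmax_tie_reports_lowest_index(self):
        # symmetric path: all scores zero -> node 0 reported
        res = score_all_nodes(make_ensemble_from_edges([[(0, 1), (1, 2)]] * 2, k=3))
        assert res.branch_node == 0


class TestMeanTreeDistance:
    def test_hop_counts_on_unit_path(self):
        ens = make_ensemble_from_edges([[(0, 1), (1, 2), (2, 3)]], k=4)
        d = mean_tree_distance(ens, 0)
        assert d.tolist() == [0.0, 1.0, 2.0, 3.0]

    def test_mean_over_trees(self):
        ens = make_ensemble_from_edges([[(0, 1, 2.0)], [(0, 1, 4.0)]], k=2)
        assert mean_tree_distance(ens, 0)[1] == pytest.approx(3.0)


class TestMarkerAnova:
    def test_separated_means_highly_significant(self, rng):
        a = rng.normal(0.0, 1.0, size=(100, 3))
        b = rng.normal(0.0, 1.0, size=(100, 3))
        b[:, 0] += 5.0  # species 0 differs by 5 sigma
        values = np.vstack([a, b])
        branches = np.array([0] * 100 + [1] * 100)
        out = marker_anova(values, branches, species_names=["s0", "s1", "s2"])
        assert out.iloc[0]["species"] == "s0"
        assert out.iloc[0]["p_bonferroni"] < 1e-6
        assert (out["p_bonferroni"] <= 1.0).all()
        # independent F statistic for the separated species
        ga, gb = values[branches == 0, 0], values[branches == 1, 0]
        grand = values[:, 0].mean()
        ssb = 100 * ((ga.mean() - grand) ** 2 + (gb.mean() - grand) ** 2)
        ssw = ((ga - ga.mean()) ** 2).sum() + ((gb - gb.mean()) ** 2).sum()
        f_manual = (ssb / 1) / (ssw / 198)
        assert out.set_index("species").loc["s0", "F"] == pytest.approx(f_manual)

    def test_identical_groups_not_significant(self, rng):
        values = rng.normal(size=(60, 2))
        branches = np.array([0, 1] * 30)
        out = marker_anova(values, branches)
        assert (out["p"] > 0.01).all()

    def test_small_branch_excluded_with_warning(self, rng):
        values = rng.normal(size=(41, 2))
        branches = np.array([0] * 20 + [1] * 20 + [2])
        with pytest.warns(UserWarning, match="fewer than 2"):
            marker_anova(values, branches)


class TestNMI:
    def test_identical_labelings(self):
        assert normalized_mutual_information([0, 0, 1, 1], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_constant_labeling_zero(self):
        assert normalized_mutual_information([0, 0, 0, 0], [0, 1, 2, 3]) == 0.0

    def test_independent_partitions_zero(self):
        assert normalized_mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_excludes_missing_labels(self):
        val = normalized_mutual_information(
            ["a", "a", "b", "b", "ungated"], [1, 1, 2, 2, 2], exclude=("ungated",)
        )
        assert val == pytest.approx(1.0)

    def test_matches_sklearn_arithmetic_average(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, size=50)
            b = rng.integers(0, 3, size=50)
            ours = normalized_mutual_information(a, b)
            theirs = normalized_mutual_info_score(a, b, average_method="arithmetic")
            assert ours == pytest.approx(theirs, abs=1e-10)
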