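import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nclvkit import phyletics as ph
from nclvkit.synthetic_data import gen_phyletic_profiles


def four_point_matrix():
    """d(A,B)=d(C,D)=1, all cross distances 10."""
    labels = list("ABCD")
    d = pd.DataFrame(10.0, index=labels, columns=labels)
    for t in labels:
        d.loc[t, t] = 0.0
    d.loc["A", "B"] = d.loc["B", "A"] = 1.0
    d.loc["C", "D"] = d.loc["D", "C"] = 1.0
    return d


class TestBuildMatrix:
    def test_presence_not_count(self):
        t = pd.DataFrame({"protein_id": ["p1", "p2", "p3"],
                          "family_id": ["F", "F", "F"], "evalue": [1e-9] * 3})
        m = ph.build_matrix({"tax1": t})
        assert m.loc["tax1", "F"] == 1

    def test_allzero_column_retained_with_universe(self):
        m = ph.build_matrix({"t1": ["F1"]}, universe=["F1", "F2"])
        assert list(m.columns) == ["F1", "F2"]
        assert m.loc["t1", "F2"] == 0

    def test_disjoint_families_give_identity_blocks(self):
        m = ph.build_matrix({"t1": ["F1"], "t2": ["F2"]})
        assert m.loc["t1", "F1"] == 1 and m.loc["t1", "F2"] == 0
        assert m.loc["t2", "F2"] == 1 and m.loc["t2", "F1"] == 0

    def test_empty_taxon_set_errors(self):
        with pytest.raises(ValueError):
            ph.build_matrix({})


class TestEuclideanDistances:
    def test_identical_rows_distance_zero(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["a", "b"],
                         columns=["f1", "f2", "f3"])
        assert ph.euclidean_distances(m).loc["a", "b"] == 0.0

    def test_two_mismatches_give_sqrt2(self):
        m = pd.DataFrame([[1, 0, 1, 1], [1, 1, 0, 1]], index=["a", "b"],
                         columns=list("wxyz"))
        assert ph.euclidean_distances(m).loc["a", "b"] == pytest.approx(math.sqrt(2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, size=(6, 20))
        m = pd.DataFrame(x, index=[f"t{i}" for i in range(6)],
                         columns=[f"f{j}" for j in range(20)])
        d = ph.euclidean_distances(m)
        for i in range(6):
            for j in range(6):
                expected = math.sqrt(sum((int(x[i, k]) - int(x[j, k])) ** 2
                                         for k in range(20)))
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = pd.DataFrame(rng.integers(0, 2, size=(7, 15)),
                         index=[f"t{i}" for i in range(7)])
        d = ph.euclidean_distances(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestHierarchicalCluster:
    def test_four_point_worked_example(self):
        tree = ph.hierarchical_cluster(four_point_matrix(), "complete")
        assert tree.height == pytest.approx(10.0)
        left, right = tree.children
        assert sorted(left.leaves()) == ["A", "B"] and left.height == pytest.approx(1.0)
        assert sorted(right.leaves()) == ["C", "D"] and right.height == pytest.approx(1.0)

    def test_identical_taxa_merge_at_zero(self):
        m = pd.DataFrame([[1, 0], [1, 0], [0, 1]], index=["a", "b", "c"],
                         columns=["f1", "f2"])
        tree = ph.hierarchical_cluster(ph.euclidean_distances(m))
        first = min((n for n in _internal_nodes(tree)), key=lambda n: n.height)
        assert first.height == 0.0 and sorted(first.leaves()) == ["a", "b"]

    def test_fewer_than_two_taxa_errors(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            ph.hierarchical_cluster(d)

    @pytest.mark.parametrize("linkage", ph.LINKAGES)
    def test_heights_monotone_along_root_paths(self, linkage):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = pd.DataFrame(rng.integers(0, 2, size=(8, 30)),
                             index=[f"t{i}" for i in range(8)])
            tree = ph.hierarchical_cluster(ph.euclidean_distances(m), linkage)
            _assert_monotone(tree)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.integers(0, 2, size=(8, 25)),
                         index=[f"t{i}" for i in range(8)])
        d = ph.euclidean_distances(m)
        ref = ph.to_newick(ph.hierarchical_cluster(d, "average"))
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(8)
            dp = d.iloc[perm, perm]
            assert ph.to_newick(ph.hierarchical_cluster(dp, "average")) == ref

    @pytest.mark.parametrize("linkage", ph.LINKAGES)
    def test_agrees_with_scipy_on_distinct_distances(self, linkage):
        """Cross-check against scipy on matrices with no ties, where the
        merge sequence is unique and tie-breaking cannot differ."""
        from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 7
            cond = rng.random(n * (n - 1) // 2) + 0.1
            d = squareform(cond)
            labels = [f"t{i}" for i in range(n)]
            df = pd.DataFrame(d, index=labels, columns=labels)
            tree = ph.hierarchical_cluster(df, linkage)
            z = scipy_linkage(cond, method=linkage)
            ours = sorted(n.height for n in _internal_nodes(tree))
            theirs = sorted(z[:, 2])
            assert np.allclose(ours, theirs)
            for k in (2, 3):
                sc = cut_tree(z, n_clusters=k).ravel()
                sc_parts = sorted(
                    sorted(labels[i] for i in range(n) if sc[i] == c)
                    for c in set(sc)
                )
                our_parts = sorted(sorted(p) for p in ph.cut_clusters(tree, k))
                assert our_parts == sc_parts


def _internal_nodes(node):
    if node.is_leaf:
        return
    yield node
    for c in node.children:
        yield from _internal_nodes(c)


def _assert_monotone(node):
    if node.is_leaf:
        return
    for c in node.children:
        assert c.height <= node.height + 1e-9
        _assert_monotone(c)


class TestNewick:
    def test_single_merge(self):
        tree = ph.hierarchical_cluster(
            pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        )
        assert ph.to_newick(tree) == "(A:2,B:2);"

    def test_four_point_serialization(self):
        tree = ph.hierarchical_cluster(four_point_matrix(), "complete")
        assert ph.to_newick(tree) == "((A:1,B:1):9,(C:1,D:1):9);"

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_parse_equality(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 2, size=(6, 20)),
                         index=[f"t{i}" for i in range(6)])
        tree = ph.hierarchical_cluster(ph.euclidean_distances(m), "average")
        assert ph.from_newick(ph.to_newick(tree)) == tree


class TestCutClusters:
    def test_k_extremes(self):
        tree = ph.hierarchical_cluster(four_point_matrix())
        assert ph.cut_clusters(tree, 1) == [{"A", "B", "C", "D"}]
        assert ph.cut_clusters(tree, 4) == [{"A"}, {"B"}, {"C"}, {"D"}]

    def test_k2_splits_at_root(self):
        tree = ph.hierarchical_cluster(four_point_matrix())
        assert ph.cut_clusters(tree, 2) == [{"A", "B"}, {"C", "D"}]

    def test_invalid_k_errors(self):
        tree = ph.hierarchical_cluster(four_point_matrix())
        with pytest.raises(ValueError):
            ph.cut_clusters(tree, 5)

    def test_recovers_planted_groups_without_noise(self):
        m, truth = gen_phyletic_profiles(4, 5, 100, 0.2, 0.0, seed=1)
        tree = ph.hierarchical_cluster(ph.euclidean_distances(m))
        assert sorted(map(sorted, ph.cut_clusters(tree, 4))) == sorted(
            map(sorted, truth.groups())
        )


MATRIX = pd.DataFrame(
    [[1, 0, 1, 0], [0, 0, 1, 0], [1, 1, 0, 0], [0, 1, 0, 0]],
    index=["croV", "mimi", "ecoli", "bsub"],
    columns=["F1", "F2", "F3", "F4"],
)


class TestRestrictAndDiscriminants:
    def test_restrict_drops_families_absent_from_group(self):
        out = ph.restrict_to_group(MATRIX, ["croV", "mimi"])
        assert list(out.columns) == ["F1", "F3"]
        assert list(out.index) == list(MATRIX.index)

    def test_restrict_empty_group_errors(self):
        with pytest.raises(ValueError):
            ph.restrict_to_group(MATRIX, [])

    def test_differences_basic(self):
        assert ph.phyletic_differences(MATRIX, "croV", "mimi") == {"F1"}
        assert ph.phyletic_differences(MATRIX, "croV", "croV") == set()

    def test_differences_respect_subset(self):
        assert ph.phyletic_differences(MATRIX, "croV", "ecoli", ["F1", "F4"]) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_difference_count_equals_squared_distance(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 2, size=(4, 30)),
                         index=["a", "b", "c", "d"],
                         columns=[f"f{j}" for j in range(30)])
        d = ph.euclidean_distances(m)
        for s, t in itertools.combinations(m.index, 2):
            n_diff = len(ph.phyletic_differences(m, s, t))
            assert n_diff == pytest.approx(d.loc[s, t] ** 2, abs=1e-9)

    def test_focal_identical_to_group_gives_empty(self):
        m = pd.DataFrame([[1, 0], [1, 0], [1, 0]], index=["x", "g1", "g2"],
                         columns=["F1", "F2"])
        assert ph.focal_discriminant(m, "x", ["g1", "g2"]) == set()

    def test_focal_zero_against_unanimous_group(self):
        m = pd.DataFrame(
            [[0]] + [[1]] * 5,
            index=["x"] + [f"g{i}" for i in range(5)],
            columns=["F1"],
        )
        assert ph.focal_discriminant(m, "x", [f"g{i}" for i in range(5)]) == {"F1"}

    def test_even_split_excluded_under_strict_majority(self):
        m = pd.DataFrame(
            [[0], [1], [1], [0], [0]],
            index=["x", "g1", "g2", "g3", "g4"],
            columns=["F1"],
        )
        assert ph.focal_discriminant(m, "x", ["g1", "g2", "g3", "g4"]) == set()


def test_order_by_clustering_reorders_both_axes():
    out = ph.order_by_clustering(MATRIX)
    assert sorted(out.index) == sorted(MATRIX.index)
    assert sorted(out.columns) == sorted(MATRIX.columns)
    tree = ph.hierarchical_cluster(ph.euclidean_distances(MATRIX))
    assert list(out.index) == ph.leaf_order(tree)
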