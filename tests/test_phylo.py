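import numpy as np
import pytest
from hypothesis import given, strategies as st

import hostislands as hi
from hostislands.errors import NewickParseError, ValidationError

from oracle_helpers import brute_force_patristic, recursive_nodal_values


class TestNewickIngestion:
    def test_parses_tree_with_tip_and_child_counts(self, tree3):
        tips = [lf.taxon.label for lf in tree3.leaf_node_iter()]
        assert sorted(tips) == ["A", "B", "C"]
        assert len(tree3.seed_node.child_nodes()) == 2

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate.*A"):
            hi.tree_from_string("((A:1,A:1):1,C:2);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValidationError, match="branch length"):
            hi.tree_from_string("((A:1,B):1,C:2);")

    def test_malformed_newick_raises_parse_error(self):
        with pytest.raises(NewickParseError):
            hi.tree_from_string("((A:1,B:1:1,C:2);")

    def test_read_newick_roundtrip(self, tmp_path, tree3):
        path = tmp_path / "t.nwk"
        tree3.write(path=str(path), schema="newick")
        again = hi.read_newick(str(path))
        assert {lf.taxon.label for lf in again.leaf_node_iter()} == {"A", "B", "C"}


class TestCophenetic:
    def test_hand_oracle_three_tips(self, tree3):
        dm = hi.cophenetic_distances(tree3)
        assert dm.get("A", "B") == pytest.approx(2.0)
        assert dm.get("A", "C") == pytest.approx(4.0)
        assert dm.get("B", "C") == pytest.approx(4.0)
        assert dm.get("A", "A") == 0.0

    def test_matches_brute_force_path_enumeration(self):
        tree = hi.simulate_tree(50, seed=5)
        dm = hi.cophenetic_distances(tree)
        labels = dm.labels
        rng = np.random.default_rng(0)
        for i, j in rng.integers(0, 50, size=(40, 2)):
            if i == j:
                continue
            expected = brute_force_patristic(tree, labels[i], labels[j])
            assert dm.get(labels[i], labels[j]) == pytest.approx(expected)

    def test_triangle_inequality_and_symmetry(self, yule200):
        dm = hi.cophenetic_distances(yule200)
        d = dm.values
        assert np.allclose(d, d.T)
        rng = np.random.default_rng(1)
        for i, j, k in rng.integers(0, 200, size=(100, 3)):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_ultrametric_tree_has_equal_root_tip_depths(self, yule200):
        depths = [lf.distance_from_root()
                  for lf in yule200.leaf_node_iter()]
        assert np.ptp(depths) < 1e-6


class TestPolytomyResolution:
    def test_binary_tree_distances_unchanged(self, balanced4):
        out = hi.resolve_polytomies(balanced4, seed=1)
        assert all(len(n.child_nodes()) == 2
                   for n in out.preorder_internal_node_iter())
        before = hi.cophenetic_distances(balanced4)
        after = hi.cophenetic_distances(out)
        assert np.allclose(before.values, after.values)

    def test_three_child_node_gains_zero_length_internal(self):
        tree = hi.tree_from_string("((A:1,B:1,C:1):1,D:2);")
        out = hi.resolve_polytomies(tree, seed=3)
        internals = list(out.preorder_internal_node_iter())
        assert all(len(n.child_nodes()) == 2 for n in internals)
        assert len(internals) == 3  # one extra node vs the input's two

    def test_polytomous_tree_distances_preserved(self):
        newick = "((A:1,B:1,C:2,D:1):1,(E:1,F:1,G:1):2,(H:3,I:1):1,J:4);"
        tree = hi.tree_from_string(newick)
        before = hi.cophenetic_distances(tree)
        after = hi.cophenetic_distances(hi.resolve_polytomies(tree, seed=11))
        assert before.labels == after.labels
        assert np.allclose(before.values, after.values)


class TestBrownianSimulation:
    def test_zero_branch_lengths_give_zero_values(self):
        tree = hi.tree_from_string("((A:0,B:0):0,C:0);")
        vals = hi.simulate_brownian(tree, sigma2=1.0, seed=4)
        assert all(v == 0.0 for v in vals.values())

    def test_same_seed_reproduces(self, yule200):
        a = hi.simulate_brownian(yule200, 1.0, seed=9)
        b = hi.simulate_brownian(yule200, 1.0, seed=9)
        assert a == b

    def test_negative_rate_rejected(self, tree3):
        with pytest.raises(ValidationError):
            hi.simulate_brownian(tree3, -1.0, seed=0)

    def test_sister_tip_covariance_matches_shared_path(self):
        # two sisters on a long shared stem: Cov = sigma2 * stem length
        tree = hi.tree_from_string("((A:1,B:1):10,C:11);")
        index = hi.TreeIndex(tree)
        tips = index.brownian_tips(2000, 1.0, np.random.default_rng(12))
        ia, ib = index.labels.index("A"), index.labels.index("B")
        cov = np.cov(tips[ia], tips[ib])[0, 1]
        # shared path is the 10 Myr stem; SE of a 2000-rep covariance ~ 0.35
        assert cov == pytest.approx(10.0, abs=3 * 0.35)

    def test_tip_variance_matches_depth(self):
        tree = hi.tree_from_string("((A:1,B:1):10,C:11);")
        index = hi.TreeIndex(tree)
        tips = index.brownian_tips(2000, 2.0, np.random.default_rng(13))
        ia = index.labels.index("A")
        assert np.var(tips[ia]) == pytest.approx(22.0, rel=0.15)


class TestNodalEstimation:
    def test_hand_oracle_balanced_cherries(self, balanced4):
        vals = hi.estimate_nodal_values(balanced4,
                                        dict(A=1, B=1, C=0, D=0))
        by_node = {}
        for node, v in vals.items():
            key = frozenset(lf.taxon.label for lf in node.leaf_iter())
            by_node[key] = v
        assert by_node[frozenset("AB")] == pytest.approx(1.0)
        assert by_node[frozenset("CD")] == pytest.approx(0.0)
        assert by_node[frozenset("ABCD")] == pytest.approx(0.5)

    def test_constant_values_propagate(self, balanced4):
        vals = hi.estimate_nodal_values(balanced4,
                                        dict(A=3.5, B=3.5, C=3.5, D=3.5))
        assert all(v == pytest.approx(3.5) for v in vals.values())

    def test_zero_length_cherry_averages(self):
        tree = hi.tree_from_string("((A:0,B:0):1,C:2);")
        vals = hi.estimate_nodal_values(tree, dict(A=0.0, B=1.0, C=0.0))
        cherry = next(v for node, v in vals.items()
                      if not node.is_leaf() and node.parent_node is not None)
        assert cherry == pytest.approx(0.5)

    def test_missing_tip_value_names_tip(self, balanced4):
        with pytest.raises(ValidationError, match="D"):
            hi.estimate_nodal_values(balanced4, dict(A=1, B=0, C=1))

    def test_matches_recursive_oracle_on_random_tree(self):
        tree = hi.simulate_tree(20, seed=21)
        rng = np.random.default_rng(2)
        tip_vals = {lf.taxon.label: float(rng.normal())
                    for lf in tree.leaf_node_iter()}
        ours = hi.estimate_nodal_values(tree, tip_vals)
        oracle = recursive_nodal_values(tree, tip_vals)
        for node, v in ours.items():
            assert v == pytest.approx(oracle[id(node)], abs=1e-10)

    @given(alpha=st.floats(-5, 5), beta=st.floats(-5, 5))
    def test_linearity(self, alpha, beta):
        tree = hi.simulate_tree(12, seed=33)
        rng = np.random.default_rng(4)
        x = {lf.taxon.label: float(rng.normal())
             for lf in tree.leaf_node_iter()}
        base = hi.estimate_nodal_values(tree, x)
        scaled = hi.estimate_nodal_values(
            tree, {k: alpha * v + beta for k, v in x.items()})
        for node in base:
            assert scaled[node] == pytest.approx(
                alpha * base[node] + beta, abs=1e-8)
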