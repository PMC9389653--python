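import numpy as np
import pytest

from httdetect import treeops as to
from helpers import (
    brute_force_parsimony,
    random_binary_tree,
    random_labels,
    random_tree_newick,
)


class TestNewickIO:
    def test_supports_parsed_fraction(self):
        st = to.read_newick("((A,B)0.95,(C,D)0.6);")
        sups = sorted(
            n.support for n in st.tree.preorder_internal_node_iter()
            if n.support is not None
        )
        assert sups == [0.6, 0.95]

    def test_percent_dialect_normalized(self):
        st = to.read_newick("((A,B)95,(C,D)60);")
        assert st.dialect == "percent"
        sups = sorted(
            n.support for n in st.tree.preorder_internal_node_iter()
            if n.support is not None
        )
        assert sups == [0.60, 0.95]

    def test_round_trip_preserves_everything(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            nwk = random_tree_newick(rng, n, with_lengths=True, with_supports=True)
            st = to.read_newick(nwk)
            st2 = to.read_newick(to.write_newick(st))
            assert to.same_unrooted_topology(st, st2)
            for a, b in zip(st.tree.preorder_node_iter(),
                            st2.tree.preorder_node_iter()):
                assert getattr(a, "support", None) == getattr(b, "support", None)
                if a.edge.length is not None:
                    assert b.edge.length == pytest.approx(a.edge.length)

    def test_unparsable_errors(self):
        with pytest.raises(ValueError, match="Newick"):
            to.read_newick("((A,B);")


class TestCollapse:
    def test_single_contraction_makes_polytomy(self):
        st = to.collapse_low_support(to.read_newick("((A,B)0.65,C);"))
        root = st.tree.seed_node
        assert len(root.child_nodes()) == 3
        assert sorted(st.leaf_names()) == ["A", "B", "C"]

    def test_high_supports_unchanged(self):
        src = to.read_newick("((A,B)0.95,(C,D)0.7);")
        out = to.collapse_low_support(src)
        assert to.same_unrooted_topology(src, out)

    def test_postcondition_scan_and_idempotence(self, rng):
        for _ in range(30):
            nwk = random_tree_newick(rng, int(rng.integers(5, 15)),
                                     with_supports=True)
            st = to.read_newick(nwk)
            out = to.collapse_low_support(st, 0.7)
            for node in out.tree.preorder_internal_node_iter(exclude_seed_node=True):
                assert node.support is None or node.support >= 0.7
            assert out.leaf_names() == st.leaf_names()
            again = to.collapse_low_support(out, 0.7)
            assert to.same_unrooted_topology(again, out)

    def test_contraction_drops_edge_length(self):
        st = to.read_newick("((A:1,B:2)0.5:3,C:4);")
        out = to.collapse_low_support(st)
        d = to.tree_distance_matrix(out, ["A", "B", "C"])
        assert d[0, 1] == pytest.approx(3.0)  # sibling path kept
        assert d[0, 2] == pytest.approx(5.0)  # contracted edge removed


class TestParsimony:
    def test_monophyletic_two_labels(self):
        st = to.read_newick("((A,B),(C,D));")
        res = to.parsimony_transitions(
            st, {"A": "x", "B": "x", "C": "y", "D": "y"}, root_mode="keep")
        assert (res.parsimony_score, res.excess_events) == (1, 0)

    def test_interleaved_labels(self):
        st = to.read_newick("((A,C),(B,D));")
        res = to.parsimony_transitions(
            st, {"A": "x", "B": "x", "C": "y", "D": "y"}, root_mode="keep")
        assert (res.parsimony_score, res.excess_events) == (2, 1)

    def test_uniform_labels_zero(self):
        st = to.read_newick("((A,B),(C,D));")
        res = to.parsimony_transitions(st, dict.fromkeys("ABCD", "x"),
                                       root_mode="keep")
        assert res.parsimony_score == 0 and res.excess_events == 0

    def test_unlabeled_leaf_named_in_error(self):
        st = to.read_newick("((A,B),(C,D));")
        with pytest.raises(KeyError, match="D"):
            to.parsimony_transitions(st, {"A": "x", "B": "x", "C": "y"})

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(80):
            n = int(rng.integers(4, 13))
            st = to.read_newick(random_tree_newick(rng, n, polytomy_prob=0.4,
                                                   with_lengths=False))
            labels = random_labels(rng, n, int(rng.integers(2, 5)))
            res = to.parsimony_transitions(st, labels, root_mode="keep")
            assert res.parsimony_score == brute_force_parsimony(st, labels)
            assert len(res.transition_edges) == res.parsimony_score
            assert res.excess_events >= 0

    def test_score_invariant_to_rooting(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            st = to.read_newick(random_tree_newick(rng, n))
            labels = random_labels(rng, n, 3)
            scores = {
                to.parsimony_transitions(st, labels, root_mode=m).parsimony_score
                for m in ("keep", "midpoint", "largest-class")
            }
            assert len(scores) == 1


class TestIncongruences:
    def test_interleaved_reports_two_transitions(self):
        st = to.read_newick("((A,C),(B,D));")
        incs = to.enumerate_incongruences(
            st, {"A": "x", "B": "x", "C": "y", "D": "y"}, root_mode="keep")
        assert len(incs) == 2

    def test_congruent_tree_all_basal(self):
        st = to.read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        labels = {"A": "x", "B": "x", "C": "y", "D": "y",
                  "E": "z", "F": "z", "G": "w", "H": "w"}
        incs = to.enumerate_incongruences(st, labels, root_mode="keep")
        assert len(incs) == len(set(labels.values())) - 1
        assert all(i.basal_origin for i in incs)
        assert [i for i in incs if not i.basal_origin] == []

    def test_totals_consistent_with_score(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 12))
            st = to.read_newick(random_tree_newick(rng, n, polytomy_prob=0.3,
                                                   with_lengths=False))
            labels = random_labels(rng, n, int(rng.integers(2, 5)))
            res = to.parsimony_transitions(st, labels, root_mode="keep")
            incs = to.enumerate_incongruences(st, labels, root_mode="keep")
            assert len(incs) == res.parsimony_score
            n_basal = sum(i.basal_origin for i in incs)
            assert len(incs) - n_basal == res.parsimony_score - n_basal
            assert all(
                len({labels[lf] for lf in i.focal_clade}) == 1 for i in incs
            )
            assert all(i.focal_label != i.context_label for i in incs)

    def test_simulator_truth_recovery_three_events(self):
        from httdetect import synthetic_data as syn

        cfg = syn.recent_ht_scenario(seed=11, n_events=3)
        res = syn.simulate(cfg)
        labels = res.labels("order")
        incs = [i for i in to.enumerate_incongruences(res.true_tree, labels)
                if not i.basal_origin]
        recipients = {e["recipient"] + "_TE" for e in res.truth["events"]}
        focal = set().union(*(i.focal_clade for i in incs))
        assert focal == recipients
        assert len(incs) == 3


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        src = to.read_newick("((A:1,B:2):1,(C:3,D:1));")
        ids = ["A", "B", "C", "D"]
        d = to.tree_distance_matrix(src, ids)
        out = to.neighbor_joining(d, ids)
        assert to.same_unrooted_topology(src, out)
        d2 = to.tree_distance_matrix(out, ids)
        assert np.allclose(d, d2, atol=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        out = to.neighbor_joining(d, ["A", "B", "C"])
        d2 = to.tree_distance_matrix(out, ["A", "B", "C"])
        assert np.allclose(d, d2, atol=1e-9)

    def test_invalid_input_errors(self):
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            to.neighbor_joining(bad, list("ABC"))
        with pytest.raises(ValueError, match="diagonal"):
            to.neighbor_joining(np.ones((3, 3)), list("ABC"))
        with pytest.raises(ValueError, match="3"):
            to.neighbor_joining(np.zeros((2, 2)), list("AB"))

    def test_recovers_random_binary_topologies(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 10))
            src = random_binary_tree(rng, n)
            ids = src.leaf_names()
            d = to.tree_distance_matrix(src, ids)
            out = to.neighbor_joining(d, ids)
            assert to.same_unrooted_topology(src, out)
            assert np.allclose(to.tree_distance_matrix(out, ids), d, atol=1e-9)

    def test_ultrametric_matches_single_linkage(self, rng):
        # on an ultrametric matrix, NJ groups the closest pair first, as
        # single-linkage does; check the induced topology
        from scipy.cluster.hierarchy import linkage, to_tree
        from scipy.spatial.distance import squareform

        for seed in range(10):
            r = np.random.default_rng(seed)
            # random ultrametric via a random coalescent-like tree
            nwk = random_tree_newick(r, 6, polytomy_prob=0.0, with_lengths=False)
            st = to.read_newick(nwk)
            # assign ultrametric depths
            for node in st.tree.postorder_node_iter():
                node.depth = 0.0 if node.is_leaf() else max(
                    c.depth for c in node.child_nodes()) + float(r.uniform(0.5, 1.5))
            for node in st.tree.preorder_node_iter():
                if node.parent_node is not None:
                    node.edge.length = node.parent_node.depth - node.depth
            ids = st.leaf_names()
            d = to.tree_distance_matrix(st, ids)
            out = to.neighbor_joining(d, ids)
            assert to.same_unrooted_topology(st, out)

            def leaves(node):
                if node.is_leaf():
                    return frozenset([ids[node.id]])
                return leaves(node.get_left()) | leaves(node.get_right())

            def clusters(node, acc):
                if not node.is_leaf():
                    acc.add(leaves(node))
                    clusters(node.get_left(), acc)
                    clusters(node.get_right(), acc)
                return acc

            sl = to_tree(linkage(squareform(d), method="single"))
            sl_clusters = {c for c in clusters(sl, set()) if len(c) < len(ids) - 1}
            nj_splits = set()
            for node in out.tree.preorder_internal_node_iter(exclude_seed_node=True):
                nj_splits.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
            for c in sl_clusters:
                assert c in nj_splits or frozenset(ids) - c in nj_splits
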