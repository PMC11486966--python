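"""Maximum-parsimony trees, diversity statistics and the CCR/linear call."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecarto import phylogeny as ph
from clonecarto.errors import NotClassifiableError, ValidationError
from clonecarto.trees import CloneTree, rooted_rf_distance


def _frame(rows, columns):
    return pd.DataFrame(rows, index=[f"T{i}" for i in range(len(rows))],
                        columns=columns)


class TestBuildTree:
    def test_perfect_phylogeny_with_internal_taxon(self):
        m = pd.DataFrame([[1, 0, 0], [1, 1, 0], [1, 0, 1]],
                         index=["A", "B", "C"], columns=["e1", "e2", "e3"])
        tree = ph.build_tree(m)
        assert ph.total_branch_length(tree) == 3
        a = tree.find_taxon("A")
        assert {c.name for c in a.children} == {"B", "C"}
        assert tree.depth(a) == 1

    def test_single_subclone_chain(self):
        m = pd.DataFrame([[1] * 5], index=["only"], columns=list("abcde"))
        tree = ph.build_tree(m)
        assert ph.total_branch_length(tree) == 5
        assert tree.depth(tree.find_taxon("only")) == 5

    def test_empty_matrix_gives_root_only_taxon(self):
        tree = ph.build_tree(pd.DataFrame(index=["z"], columns=[]))
        assert ph.total_branch_length(tree) == 0

    def test_conflict_free_score_equals_event_count(self):
        rng = np.random.default_rng(7)
        # build a random laminar family: nested/disjoint carrier sets
        m = pd.DataFrame(0, index=[f"T{i}" for i in range(5)],
                         columns=[f"e{i}" for i in range(6)])
        m.loc[:, "e0"] = 1
        m.loc[["T0", "T1"], "e1"] = 1
        m.loc[["T0"], "e2"] = 1
        m.loc[["T2", "T3", "T4"], "e3"] = 1
        m.loc[["T3"], "e4"] = 1
        m.loc[["T4"], "e5"] = 1
        tree = ph.build_tree(m)
        assert ph.total_branch_length(tree) == 6  # zero homoplasy

    def test_conflicting_matrix_minimizes_changes(self):
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 0, 1]],
                         index=["P", "Q", "R"], columns=["a", "b", "c"])
        tree = ph.build_tree(m)
        # any topology needs 5 changes for this incompatible triple
        assert ph.total_branch_length(tree) == 5

    def test_duplicate_rows_collapse(self):
        m = pd.DataFrame([[1, 0], [1, 0], [1, 1]],
                         index=["A", "B", "C"], columns=["e1", "e2"])
        tree = ph.build_tree(m)
        merged = [t.name for t in tree.taxa() if "+" in t.name]
        assert merged == ["A+B"]

    def test_deterministic(self):
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 0, 1]],
                         index=["P", "Q", "R"], columns=["a", "b", "c"])
        assert ph.build_tree(m).newick() == ph.build_tree(m).newick()


class TestIgd:
    def test_direct_ratio(self):
        tree = CloneTree()
        node = tree.root
        for i in range(4):  # stem of length 4
            node = tree.add_child(node, events=(f"s{i}",))
        x = tree.add_child(node, events=("x",), name="X")
        y = tree.add_child(node, events=("y",), name="Y")
        assert ph.igd(tree, ["X", "Y"]) == pytest.approx(2 / 10)

    def test_single_taxon_is_zero(self, two_timepoint_tree):
        assert ph.igd(two_timepoint_tree, ["B"]) == 0.0

    def test_mrca_at_root_gives_one(self):
        tree = CloneTree()
        tree.add_child(tree.root, events=("a", "b"), name="A")
        tree.add_child(tree.root, events=("c",), name="B")
        assert ph.igd(tree, ["A", "B"]) == 1.0

    def test_zero_depth_subset_is_an_error(self):
        tree = CloneTree()
        tree.add_child(tree.root, events=(), name="A")
        with pytest.raises(ValidationError):
            ph.igd(tree, ["A"])

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_bounds_on_random_trees(self, data):
        """0 <= IGD <= 1 for random trees and random taxon subsets."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        tree = CloneTree()
        nodes = [tree.root]
        names = []
        for i in range(int(rng.integers(2, 10))):
            parent = nodes[int(rng.integers(0, len(nodes)))]
            n_events = int(rng.integers(1, 4))
            node = tree.add_child(parent, events=[f"e{i}_{j}" for j in range(n_events)],
                                  name=f"T{i}")
            nodes.append(node)
            names.append(f"T{i}")
        k = int(rng.integers(1, len(names) + 1))
        subset = list(rng.choice(names, size=k, replace=False))
        value = ph.igd(tree, subset)
        assert 0.0 <= value <= 1.0


class TestIrregularity:
    def test_star_symmetry(self):
        tree = CloneTree()
        stem = tree.add_child(tree.root, events=("s1", "s2"))
        for i in range(3):
            tree.add_child(stem, events=(f"p{i}", f"q{i}"), name=f"T{i}")
        assert ph.irregularity(tree) == 0.0

    def test_two_taxa_sample_variance(self):
        tree = CloneTree()
        tree.add_child(tree.root, events=("a", "b"), name="A")
        tree.add_child(tree.root, events=("c", "d", "e", "f"), name="B")
        assert ph.irregularity(tree) == pytest.approx(2.0)

    def test_three_taxa(self):
        tree = CloneTree()
        tree.add_child(tree.root, events=("a",), name="A")
        tree.add_child(tree.root, events=("b", "c"), name="B")
        tree.add_child(tree.root, events=("d", "e", "f"), name="C")
        assert ph.irregularity(tree) == pytest.approx(1.0)

    def test_requires_two_taxa(self):
        tree = CloneTree()
        tree.add_child(tree.root, events=("a",), name="A")
        with pytest.raises(ValidationError):
            ph.irregularity(tree)


class TestRfDistance:
    def test_identical_trees(self, two_timepoint_tree):
        assert rooted_rf_distance(two_timepoint_tree, two_timepoint_tree) == 0

    def test_different_attachment_detected(self):
        t1 = CloneTree()
        stem = t1.add_child(t1.root, events=("s",), name="S")
        a = t1.add_child(stem, events=("a",), name="A")
        t1.add_child(a, events=("b",), name="B")
        t2 = CloneTree()
        stem2 = t2.add_child(t2.root, events=("s",), name="S")
        t2.add_child(stem2, events=("a",), name="A")
        t2.add_child(stem2, events=("b",), name="B")
        assert rooted_rf_distance(t1, t2) > 0


class TestClassifyReplacement:
    def test_collateral_replacement(self, two_timepoint_tree):
        detection = {"A": {"p1"}, "B": {"p1"}, "C": {"q1"}, "D": {"q1"}}
        call = ph.classify_replacement(two_timepoint_tree,
                                       {"p1": "pre", "q1": "post"}, detection)
        assert call.classification == "CCR"

    def test_linear_from_detected_ancestor(self, two_timepoint_tree):
        detection = {"A": {"p1"}, "B": {"q1"}, "C": {"p1"}}
        call = ph.classify_replacement(two_timepoint_tree,
                                       {"p1": "pre", "q1": "post"}, detection)
        assert call.classification == "linear"
        assert call.supported["B"] == "A"

    def test_mixed(self, two_timepoint_tree):
        detection = {"A": {"p1"}, "B": {"q1"}, "D": {"q1"}, "stem": set()}
        call = ph.classify_replacement(two_timepoint_tree,
                                       {"p1": "pre", "q1": "post"}, detection)
        assert call.classification == "mixed"

    def test_single_timepoint_not_classifiable(self, two_timepoint_tree):
        detection = {"A": {"p1"}, "B": {"p1"}}
        with pytest.raises(NotClassifiableError):
            ph.classify_replacement(two_timepoint_tree, {"p1": "pre"}, detection)

    def test_patient_mrca_not_a_witness_unless_dominant(self, two_timepoint_tree):
        # the stem population is detected pre but is the common ancestor of
        # everything; without dominance it cannot evidence linear descent
        detection = {"stem": {"p1"}, "A": {"p1"}, "C": {"q1"}, "D": {"q1"}}
        fractions = {"stem": {"p1": 0.1}, "A": {"p1": 0.9},
                     "C": {"q1": 0.3}, "D": {"q1": 0.7}}
        call = ph.classify_replacement(two_timepoint_tree,
                                       {"p1": "pre", "q1": "post"}, detection,
                                       fractions=fractions)
        assert call.classification == "CCR"
        # ... but a dominant ancestral population does
        fractions["stem"]["p1"] = 0.95
        fractions["A"]["p1"] = 0.05
        call2 = ph.classify_replacement(two_timepoint_tree,
                                        {"p1": "pre", "q1": "post"}, detection,
                                        fractions=fractions)
        assert call2.classification == "linear"
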