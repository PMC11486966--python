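"""Single-cell CNA event calling, harmonization and clone trees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecarto import scwgs as sc
from clonecarto import synthetic_data as syn
from clonecarto.errors import HarmonizationError, ValidationError


def _profile(cell_id="c", **chroms):
    return sc.CellProfile(cell_id, {k: np.array(v) for k, v in chroms.items()})


AMPLICONS = (("2", 12, 18),)


class TestCallCellEvents:
    def test_four_bin_gain_dropped(self):
        p = _profile(c7=[2] * 10 + [3] * 4 + [2] * 86)
        assert sc.call_cell_events(p) == []

    def test_five_bin_loss_called(self):
        p = _profile(c1=[1] * 5 + [2] * 95)
        events = sc.call_cell_events(p)
        assert len(events) == 1
        assert events[0].klass == "loss" and events[0].n_bins == 5

    def test_amplicon_exception_only_in_designated_region(self):
        inside = _profile(**{"2": [2] * 12 + [12] * 2 + [2] * 86})
        outside = _profile(**{"5": [2] * 12 + [12] * 2 + [2] * 86})
        assert [e.klass for e in sc.call_cell_events(inside, amplicon_regions=AMPLICONS)] == ["amplification"]
        assert sc.call_cell_events(outside, amplicon_regions=AMPLICONS) == []

    def test_adjacent_states_split_at_boundaries(self):
        p = _profile(c3=[2] * 10 + [3] * 6 + [4] * 6 + [2] * 78)
        events = sc.call_cell_events(p)
        assert [(e.copy_number, e.start_bin, e.end_bin) for e in events] == [
            (3, 10, 16), (4, 16, 22)]

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            sc.CellProfile("bad", {})

    @given(st.data())
    @settings(max_examples=150, derandomize=True)
    def test_no_event_below_class_threshold(self, data):
        """Fuzzed profiles never yield events shorter than their threshold."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        arr = np.full(60, 2)
        for _ in range(int(rng.integers(1, 6))):
            start = int(rng.integers(0, 55))
            length = int(rng.integers(1, 12))
            arr[start:start + length] = int(rng.integers(0, 13))
        p = _profile(**{"2": arr})
        for ev in sc.call_cell_events(p, amplicon_regions=AMPLICONS):
            if ev.klass == "amplification" and ev.overlaps("2", 12, 18):
                assert ev.n_bins >= 2
            else:
                assert ev.n_bins >= 5


class TestHarmonize:
    def test_identical_events_merge(self):
        ev = sc.CellEvent("3", 100, 110, 3, "gain")
        cells = {f"c{i}": [sc.CellEvent("3", 100, 110, 3, "gain")] for i in range(6)}
        catalog, matrix = sc.harmonize_events(cells)
        assert len(catalog) == 1
        assert matrix.to_numpy().sum() == 6

    def test_partial_overlap_decomposes(self):
        cells = {"a": [sc.CellEvent("3", 100, 120, 3, "gain")],
                 "b": [sc.CellEvent("3", 100, 140, 3, "gain")]}
        catalog, matrix = sc.harmonize_events(cells)
        intervals = {(e.start_bin, e.end_bin) for e in catalog}
        assert intervals == {(100, 120), (120, 140)}
        assert matrix.loc["a"].sum() == 1 and matrix.loc["b"].sum() == 2

    def test_boundary_jitter_within_tolerance_snapped(self):
        cells = {"a": [sc.CellEvent("3", 100, 120, 3, "gain")],
                 "b": [sc.CellEvent("3", 101, 119, 3, "gain")]}
        catalog, matrix = sc.harmonize_events(cells)
        assert len(catalog) == 1
        assert matrix.to_numpy().sum() == 2

    def test_disjoint_chromosomes_stay_separate(self):
        cells = {"a": [sc.CellEvent("1", 0, 10, 3, "gain")],
                 "b": [sc.CellEvent("2", 0, 10, 1, "loss")]}
        catalog, _ = sc.harmonize_events(cells)
        assert len(catalog) == 2


class TestCellTree:
    def test_nested_profiles_collapse_to_counted_chain(self):
        matrix = pd.DataFrame(
            [[1, 0]] * 6 + [[1, 1]] * 4,
            index=[f"c{i}" for i in range(10)], columns=["e1", "e2"])
        tree = sc.build_cell_tree(matrix)
        taxa = {t.name: t.cell_count for t in tree.taxa()}
        assert taxa == {"clone_1": 6, "clone_2": 4}
        deep = tree.find_taxon("clone_2")
        assert tree.depth(deep) == 2

    def test_all_identical_cells_single_taxon(self):
        matrix = pd.DataFrame([[1, 1]] * 5, index=[f"c{i}" for i in range(5)],
                              columns=["e1", "e2"])
        tree = sc.build_cell_tree(matrix)
        assert len(tree.taxa()) == 1
        assert tree.taxa()[0].cell_count == 5

    def test_collapse_does_not_change_topology(self):
        rng = np.random.default_rng(5)
        base = pd.DataFrame([[1, 0, 0], [1, 1, 0], [1, 1, 1]],
                            columns=["a", "b", "c"],
                            index=["x", "y", "z"])
        expanded = base.loc[rng.choice(["x", "y", "z"], size=20)]
        expanded.index = [f"c{i}" for i in range(20)]
        t_small = sc.build_cell_tree(base)
        t_big = sc.build_cell_tree(expanded)
        assert len(t_small.taxa()) == len(t_big.taxa())
        # same nesting depths over distinct profiles
        assert sorted(t_small.depth(t) for t in t_small.taxa()) == \
            sorted(t_big.depth(t) for t in t_big.taxa())


class TestPop:
    def test_fraction_below_matching_branches(self, two_timepoint_tree):
        for name, count in [("stem", 0), ("A", 3), ("B", 1), ("C", 2), ("D", 4)]:
            two_timepoint_tree.find_taxon(name).cell_count = count
        pop = sc.pop_statistic(two_timepoint_tree, lambda evs: "a" in evs)
        assert pop == pytest.approx(0.4)  # A and B carry branch 'a'

    def test_predicate_matching_nothing(self, two_timepoint_tree):
        for t in two_timepoint_tree.taxa():
            t.cell_count = 1
        assert sc.pop_statistic(two_timepoint_tree, lambda evs: False) == 0.0

    def test_predicate_matching_root(self, two_timepoint_tree):
        for t in two_timepoint_tree.taxa():
            t.cell_count = 2
        assert sc.pop_statistic(two_timepoint_tree, lambda evs: True) == 1.0

    def test_partition_over_first_generation_branches_sums_to_one(self, two_timepoint_tree):
        for name, count in [("stem", 2), ("A", 3), ("B", 1), ("C", 2), ("D", 4)]:
            two_timepoint_tree.find_taxon(name).cell_count = count
        # the first-generation branches below the stem partition all its progeny
        p_left = sc.pop_statistic(two_timepoint_tree, lambda evs: "a" in evs)
        p_right = sc.pop_statistic(two_timepoint_tree, lambda evs: "c" in evs)
        p_stem_only = sc.pop_statistic(
            two_timepoint_tree,
            lambda evs: "s1" in evs) - p_left - p_right
        assert p_left + p_right + p_stem_only == pytest.approx(1.0)

    def test_average_over_trees(self, two_timepoint_tree):
        for t in two_timepoint_tree.taxa():
            t.cell_count = 1
        trees = [two_timepoint_tree, two_timepoint_tree]
        assert sc.pop_statistic(trees, lambda evs: "a" in evs) == pytest.approx(0.4)


class TestCloneDynamics:
    def test_loss_over_time(self):
        m1 = pd.DataFrame([[1, 0]] * 6 + [[1, 1]] * 4,
                          index=[f"a{i}" for i in range(10)], columns=["e1", "e2"])
        m2 = pd.DataFrame([[1, 1]] * 12,
                          index=[f"b{i}" for i in range(12)], columns=["e1", "e2"])
        table = sc.clone_dynamics([("t0", m1), ("t1", m2)])
        lost = table[(table["t0"] > 0) & (table["t1"] == 0)]
        assert len(lost) == 1
        assert lost["t0"].iloc[0] == pytest.approx(0.6)

    def test_single_clone_throughout(self):
        m = pd.DataFrame([[1]] * 4, index=list("abcd"), columns=["e"])
        table = sc.clone_dynamics([("t0", m), ("t1", m)])
        assert table.shape == (1, 2)
        assert (table == 1.0).all().all()

    def test_catalog_mismatch(self):
        m1 = pd.DataFrame([[1]], index=["a"], columns=["e1"])
        m2 = pd.DataFrame([[1]], index=["b"], columns=["e2"])
        with pytest.raises(HarmonizationError):
            sc.clone_dynamics([("t0", m1), ("t1", m2)])


class TestEndToEndWithSimulator:
    def test_noise_free_cells_recover_clone_events(self):
        truth = syn.simulate_truth(n_clones=4, seed=11)
        region = truth.regions[0].name
        cells = syn.render_cells(truth, region, n_cells=40, bin_noise_rate=0.0, seed=2)
        profiles = sc.profiles_from_frame(cells)
        events = {p.cell_id: sc.call_cell_events(p) for p in profiles}
        catalog, matrix = sc.harmonize_events(events)
        tree = sc.build_cell_tree(matrix)
        # every distinct genotype in the region appears as one clone taxon
        present = [c for c in truth.clones()
                   if truth.regions[0].extant.get(c, 0.0) > 0]
        genotypes = set()
        for c in present:
            node = truth.clone_node(c)
            cnas = frozenset(e for e in node.genotype if e in truth.cna_events)
            genotypes.add(cnas)
        assert len(tree.taxa()) == len(genotypes)
        assert sum(t.cell_count for t in tree.taxa()) == 40
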