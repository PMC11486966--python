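"""Grouping of MCF patterns and subclone configuration resolution."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecarto import deconvolution as dc
from clonecarto.cna_quantification import SegmentCall, mbaf_from_msf, ratio_from_msf
from clonecarto.errors import ConfigurationError, ConstraintConflictError, ValidationError


def _matrix(rows: dict, samples=None, **kwargs):
    df = pd.DataFrame.from_dict(rows, orient="index")
    if samples:
        df = df[samples]
    return dc.MCFMatrix(values=df, **kwargs)


class TestGroupEvents:
    def test_similar_patterns_merge_and_round(self):
        m = _matrix({"e1": [1.0, 0.5, 0.0], "e2": [0.95, 0.55, 0.05]})
        groups = dc.group_events(m, tol=0.15)
        assert len(groups) == 1
        assert list(groups[0].profile.values()) == [1.0, 0.5, 0.0]

    def test_identical_patterns_merge(self):
        m = _matrix({"e1": [0.4, 0.2], "e2": [0.4, 0.2]})
        assert len(dc.group_events(m, tol=0.0)) == 1

    def test_distinct_patterns_stay_apart(self):
        m = _matrix({"e1": [1, 0, 0], "e2": [0, 1, 0]})
        assert len(dc.group_events(m, tol=0.5)) == 2

    def test_zero_tolerance_only_exact(self):
        m = _matrix({"e1": [0.40, 0.2], "e2": [0.41, 0.2]})
        assert len(dc.group_events(m, tol=0.0)) == 2

    def test_negative_tolerance(self):
        with pytest.raises(ConfigurationError):
            dc.group_events(_matrix({"e": [0.1]}), tol=-1)

    @given(st.permutations(range(4)))
    @settings(max_examples=24, derandomize=True)
    def test_order_independence(self, perm):
        """Complete-linkage grouping must not depend on event order."""
        rows = {"e1": [1.0, 0.5], "e2": [0.9, 0.45], "e3": [0.2, 0.2], "e4": [0.15, 0.3]}
        keys = list(rows)
        shuffled = {keys[i]: rows[keys[i]] for i in perm}
        ref = {frozenset(g.events) for g in dc.group_events(_matrix(rows), tol=0.15)}
        got = {frozenset(g.events) for g in dc.group_events(_matrix(shuffled), tol=0.15)}
        assert got == ref


class TestResolveConfiguration:
    def test_pigeonhole_forces_nesting(self):
        groups = dc.group_events(_matrix({"e1": [0.6, 0.8], "e2": [0.6, 0.3]}), tol=0.1)
        config = dc.resolve_configuration(groups)
        a, b = (g.group_id for g in groups)
        assert config.relation(a, b) == "nested"

    def test_disjoint_presence_stays_parallel(self):
        groups = dc.group_events(
            _matrix({"a": [0.5, 0.5, 0.0], "b": [0.5, 0.0, 0.5]}), tol=0.1)
        config = dc.resolve_configuration(groups)
        assert config.relation(groups[0].group_id, groups[1].group_id) == "parallel"

    def test_mixed_pair_never_nested(self):
        bar = {frozenset(("seg(1+3)", "seg(1+2)"))}
        groups = dc.group_events(
            _matrix({"seg(1+3)": [0.4], "seg(1+2)": [0.6]}, no_nest_pairs=bar), tol=0.1)
        config = dc.resolve_configuration(groups, no_nest_pairs=bar)
        assert config.relation(groups[0].group_id, groups[1].group_id) == "parallel"

    def test_mixed_pair_with_pigeonhole_is_a_conflict(self):
        bar = {frozenset(("x", "y"))}
        groups = dc.group_events(_matrix({"x": [0.7], "y": [0.7]}, no_nest_pairs=bar),
                                 tol=0.1)
        with pytest.raises(ConstraintConflictError):
            dc.resolve_configuration(groups, no_nest_pairs=bar)

    def test_child_fraction_bounded_by_parent(self):
        groups = dc.group_events(
            _matrix({"p": [0.9, 0.7], "c": [0.5, 0.6], "q": [0.2, 0.05]}), tol=0.1)
        config = dc.resolve_configuration(groups)
        for g in config.groups:
            parent = config.parents[g.group_id]
            if parent is not None:
                pprof = config.group(parent).profile
                for s, v in g.profile.items():
                    assert v <= pprof[s] + dc.NEST_TOL + 1e-9

    def test_antichain_cap_holds(self):
        groups = dc.group_events(
            _matrix({"a": [0.5, 0.1], "b": [0.4, 0.2], "c": [0.2, 0.6]}), tol=0.05)
        config = dc.resolve_configuration(groups)
        extant = config.extant_fractions()
        assert (extant.sum(axis=0) <= 1.0 + dc.SUM_TOL + 1e-9).all()


class TestEventMatrix:
    def test_chain_path_closure(self):
        groups = dc.group_events(
            _matrix({"e1": [1.0], "e2": [0.6], "e3": [0.3]}), tol=0.05)
        config = dc.resolve_configuration(groups)
        mat, fractions = dc.event_matrix(config)
        # rows ordered by nesting: deepest row contains all shallower events
        sums = mat.sum(axis=1).sort_values()
        assert list(sums) == [1, 2, 3]
        deepest = mat.loc[sums.index[-1]]
        assert deepest.sum() == 3

    def test_parallel_children_share_only_stem(self):
        groups = dc.group_events(
            _matrix({"s": [1.0, 1.0], "a": [0.8, 0.0], "b": [0.0, 0.8]}), tol=0.05)
        config = dc.resolve_configuration(groups)
        mat, _ = dc.event_matrix(config)
        rows = mat.to_numpy()
        a, b = [r for r in rows if r.sum() == 2]
        assert (a & b).sum() == 1  # only the stem column is shared


class TestInferMissingEvents:
    def test_lowest_allele_count_gain_becomes_stem(self):
        m = _matrix({"g12": [1.0, 0.0], "g13": [0.0, 1.0]},
                    event_meta={"g12": {"kind": "gain", "chrom": "1", "start": 1,
                                        "end": 100, "n_a": 1, "n_b": 2},
                                "g13": {"kind": "gain", "chrom": "1", "start": 1,
                                        "end": 100, "n_a": 1, "n_b": 3}})
        out = dc.infer_missing_events(m)
        assert (out.values.loc["g12"] == 1.0).all()
        assert out.event_meta["g12"]["annotation"] == "inferred_stem"

    def test_contradictory_whole_chromosome_split_private(self):
        m = _matrix({"w": [0.9, 0.1, 0.9], "o": [0.3, 0.9, 0.9]},
                    event_meta={"w": {"whole_chrom": True}, "o": {}})
        out = dc.infer_missing_events(m)
        assert "w" not in out.values.index
        privates = [e for e in out.values.index if e.startswith("w@")]
        assert len(privates) == 3
        assert all(out.event_meta[e]["annotation"] == "inferred_private" for e in privates)

    def test_consistent_matrix_unchanged(self):
        m = _matrix({"a": [1.0, 1.0], "b": [0.5, 0.4]},
                    event_meta={"a": {"whole_chrom": True}, "b": {}})
        out = dc.infer_missing_events(m)
        pd.testing.assert_frame_equal(out.values, m.values)


def _pdx_segment(sample, chrom, msf, na=1, nb=2, mbaf=None):
    return SegmentCall(sample_id=sample, chrom=chrom, start=1, end=1_000_000,
                       ratio=ratio_from_msf(msf, na + nb, 2, 2), n_a=na, n_b=nb,
                       mbaf=mbaf)


class TestPdxDeconvolve:
    def test_clonal_threshold(self):
        config = dc.pdx_deconvolve([_pdx_segment("A", "1", 0.92)])
        assert config.groups[0].profile["A"] == 1.0

    def test_parallel_margin_and_normalization(self):
        # two parallel lineages, distinguishable across samples, jointly at
        # 0.57 + 0.56 in sample A: rounded 0.6 + 0.6 = 1.2 accepted, then
        # renormalized to 0.5 + 0.5
        segs = [_pdx_segment("A", "1", 0.57), _pdx_segment("A", "2", 0.56),
                _pdx_segment("B", "1", 0.6), _pdx_segment("C", "2", 0.6)]
        config = dc.pdx_deconvolve(segs)
        profiles = sorted(g.profile.get("A", 0.0) for g in config.groups)
        assert profiles == pytest.approx([0.5, 0.5])

    def test_cnni_ordered_as_loss_from_trisomy(self):
        segs = [_pdx_segment(s, "1", 1.0) for s in ("S1", "S2", "S3", "S4", "S5")]
        segs.append(SegmentCall(sample_id="S6", chrom="1", start=1, end=1_000_000,
                                ratio=1.0, n_a=0, n_b=2, mbaf=1.0))
        config = dc.pdx_deconvolve(segs)
        cnni = next(g for g in config.groups if "(0+2)" in g.events[0])
        tri = next(g for g in config.groups if "(1+2)" in g.events[0])
        assert config.parents[cnni.group_id] == tri.group_id

    def test_private_vs_shared_annotation(self):
        segs = [_pdx_segment("A1", "1", 1.0), _pdx_segment("A2", "1", 1.0),
                _pdx_segment("A1", "2", 0.6), _pdx_segment("A2", "2", 0.6),
                _pdx_segment("B1", "1", 1.0), _pdx_segment("B2", "1", 1.0)]
        lineage = {"A1": "tumorA", "A2": "tumorA", "B1": "tumorB", "B2": "tumorB"}
        config = dc.pdx_deconvolve(segs, sample_lineage=lineage)
        annot = {g.events[0]: g.annotation for g in config.groups}
        assert annot["1:1-1000000(1+2)"] == "shared"
        assert annot["2:1-1000000(1+2)"] == "private"


class TestCollapseChains:
    def test_indistinguishable_fragments_fold(self):
        df = pd.DataFrame.from_dict(
            {"a": [1.0, 1.0], "b": [0.95, 0.9], "c": [0.3, 0.2]}, orient="index")
        groups = dc.group_events(dc.MCFMatrix(values=df), tol=0.02)
        config = dc.resolve_configuration(groups)
        assert len(config.groups) == 3
        collapsed = dc.collapse_chains(config, df, tol=0.15)
        assert len(collapsed.groups) == 2
        top = next(g for g in collapsed.groups if len(g.events) == 2)
        assert set(top.events) == {"a", "b"}

    def test_distinct_clones_untouched(self):
        df = pd.DataFrame.from_dict({"a": [1.0, 1.0], "c": [0.3, 0.2]}, orient="index")
        groups = dc.group_events(dc.MCFMatrix(values=df), tol=0.1)
        config = dc.resolve_configuration(groups)
        collapsed = dc.collapse_chains(config, df, tol=0.15)
        assert len(collapsed.groups) == 2
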