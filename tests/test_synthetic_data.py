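"""Ground-truth simulator: determinism, forward models, treatment scenarios."""

import numpy as np
import pandas as pd
import pytest

from clonecarto import synthetic_data as syn
from clonecarto.cna_quantification import msf_from_mbaf, msf_from_ratio
from clonecarto.errors import ConfigurationError, ExtinctionError


class TestSimulateTruth:
    def test_linear_mode_is_a_chain(self):
        truth = syn.simulate_truth(n_clones=4, mode="linear", seed=1)
        depths = sorted(len(truth.tree.root_path(truth.clone_node(c))) - 1
                        for c in truth.clones())
        assert depths == [1, 2, 3, 4]

    def test_branched_mode_has_parallel_lineages(self):
        truth = syn.simulate_truth(n_clones=6, mode="branched", seed=2)
        assert any(len(truth.clone_node(c).children) >= 2 for c in truth.clones())

    def test_deterministic_given_seed(self):
        a = syn.simulate_truth(n_clones=5, seed=9)
        b = syn.simulate_truth(n_clones=5, seed=9)
        assert [r.extant for r in a.regions] == [r.extant for r in b.regions]
        assert sorted(a.cna_events) == sorted(b.cna_events)
        sa, _ = syn.render_bulk(a, a.regions[0].name, seed=3)
        sb, _ = syn.render_bulk(b, b.regions[0].name, seed=3)
        pd.testing.assert_frame_equal(sa, sb)

    def test_fractions_on_tenth_grid_and_sum_to_one(self):
        truth = syn.simulate_truth(n_clones=6, seed=4)
        for reg in truth.regions:
            assert sum(reg.extant.values()) == pytest.approx(1.0)
            for f in reg.extant.values():
                assert round(f * 10) == pytest.approx(f * 10)

    def test_identifiability_conditions_hold(self):
        truth = syn.simulate_truth(n_clones=7, seed=5)
        assert syn._identifiable(truth)

    def test_invalid_rates(self):
        with pytest.raises(ConfigurationError):
            syn.simulate_truth(n_clones=3, cna_rate=0.0)


class TestRenderBulk:
    def test_noise_free_segments_follow_forward_models(self):
        truth = syn.simulate_truth(n_clones=4, seed=6)
        reg = truth.regions[0]
        segs, variants = syn.render_bulk(truth, reg.name, noise_sd=0.0, seed=0)
        for row in segs.itertuples(index=False):
            nt = row.n_a + row.n_b
            if nt != 2:
                msf = msf_from_ratio(row.ratio, nt, 2, 2)
            else:
                msf = msf_from_mbaf(row.mbaf, row.n_a, row.n_b)
            assert msf == pytest.approx(row.true_msf, abs=1e-6)

    def test_absent_clone_variants_have_zero_reads(self):
        truth = syn.simulate_truth(n_clones=5, seed=8)
        # find a clone absent from some region
        for reg in truth.regions:
            for c in truth.clones():
                if truth.cumulative(c, reg.name) == 0.0:
                    _, variants = syn.render_bulk(truth, reg.name, noise_sd=0.0,
                                                  depth=500, seed=0)
                    node = truth.clone_node(c)
                    snvs = [e for e in node.events if e in truth.snv_events]
                    if not snvs:
                        continue
                    ev = truth.snv_events[snvs[0]]
                    row = variants[(variants.chrom == ev.chrom) & (variants.pos == ev.pos)]
                    assert (row.alt_reads == 0).all()
                    return
        pytest.skip("no absent clone with an SNV in this draw")

    def test_purity_enters_the_ratio(self):
        # a clonal trisomy in a sample of purity 0.8 gives ratio 1.2
        truth = syn.simulate_truth(n_clones=3, seed=10)
        reg = truth.regions[0]
        segs, _ = syn.render_bulk(truth, reg.name, noise_sd=0.0, seed=0)
        stem_gains = segs[(segs.n_a == 1) & (segs.n_b == 2) & segs.clonal_hint]
        expected = (reg.purity * 3 + (1 - reg.purity) * 2) / 2
        assert stem_gains.ratio.iloc[0] == pytest.approx(expected)

    def test_platform_compression(self):
        truth = syn.simulate_truth(n_clones=3, seed=10)
        reg = truth.regions[0].name
        lin, _ = syn.render_bulk(truth, reg, noise_sd=0.0, seed=0)
        log, _ = syn.render_bulk(truth, reg, noise_sd=0.0, platform_factor=0.55, seed=0)
        back = 2.0 ** (log.ratio / 0.55)
        assert np.allclose(back, lin.ratio)


class TestTreatment:
    def test_uniform_weights_leave_fractions_unchanged(self):
        truth = syn.simulate_truth(n_clones=4, seed=12)
        post = syn.apply_treatment(truth, {c: 1.0 for c in truth.clones()})
        for pre_r, post_r in zip(truth.regions, post.regions):
            assert post_r.extant == pre_r.extant

    def test_killed_clones_disappear(self):
        truth = syn.simulate_truth(n_clones=4, seed=12)
        victim = truth.clones()[-1]
        weights = {c: (0.0 if c == victim else 1.0) for c in truth.clones()}
        post = syn.apply_treatment(truth, weights)
        assert all(victim not in r.extant for r in post.regions)

    def test_total_extinction_is_an_error(self):
        truth = syn.simulate_truth(n_clones=3, seed=12)
        with pytest.raises(ExtinctionError):
            syn.apply_treatment(truth, {c: 0.0 for c in truth.clones()})


class TestScenarios:
    @pytest.mark.parametrize("kind", ["ccr", "linear"])
    def test_scenario_structure(self, kind):
        scenario = syn.treatment_scenario(kind, seed=3)
        truth = scenario.truth
        assert {r.timepoint for r in truth.regions} == {"pre", "post"}
        assert syn._identifiable(truth)
        if kind == "ccr":
            # no detectable pre-treatment population is ancestral to the
            # post-treatment lineage
            pre_clones = {c for r in truth.regions if r.timepoint == "pre"
                          for c in r.extant}
            post_clones = {c for r in truth.regions if r.timepoint == "post"
                           for c in r.extant}
            assert pre_clones.isdisjoint(post_clones)
        else:
            post_dominants = {max(r.extant, key=r.extant.get)
                              for r in truth.regions if r.timepoint == "post"}
            pre_detected = {c for r in truth.regions if r.timepoint == "pre"
                            for c in r.extant}
            for d in post_dominants:
                anc = {n.name for n in truth.tree.root_path(truth.clone_node(d))
                       if n.is_taxon}
                assert anc & pre_detected

    def test_scenarios_deterministic(self):
        a = syn.treatment_scenario("ccr", seed=7)
        b = syn.treatment_scenario("ccr", seed=7)
        assert [r.extant for r in a.truth.regions] == [r.extant for r in b.truth.regions]


class TestRenderCells:
    def test_noise_free_cells_match_clone_profiles(self):
        truth = syn.simulate_truth(n_clones=3, seed=13)
        reg = truth.regions[0]
        cells = syn.render_cells(truth, reg.name, n_cells=10, bin_noise_rate=0.0, seed=0)
        # every cell's aberrant bins coincide with one clone's CNAs
        clone_profiles = set()
        for c in reg.extant:
            node = truth.clone_node(c)
            bins = []
            for eid in sorted(node.genotype):
                ev = truth.cna_events.get(eid)
                if ev and ev.nt != 2:  # copy-neutral events are dosage-invisible
                    bins.append((ev.chrom, ev.start_bin, ev.end_bin, ev.nt))
            clone_profiles.add(tuple(sorted(bins)))
        for _, row in cells.iterrows():
            aberrant = tuple(sorted(
                {(chrom, None, None, None) for (chrom, b), v in row.items() if v != 2}))
            # coarse check: the set of aberrant chromosomes matches some clone
            chroms = {c for c, *_ in aberrant}
            assert any(chroms == {c for c, *_ in prof} for prof in clone_profiles)

    def test_multinomial_counts_near_expectation(self):
        truth = syn.simulate_truth(n_clones=2, mode="linear", seed=14)
        reg = next(r for r in truth.regions if len(r.extant) == 2)
        cells = syn.render_cells(truth, reg.name, n_cells=500, bin_noise_rate=0.0, seed=1)
        profiles = cells.apply(lambda r: tuple(r), axis=1)
        sizes = sorted(profiles.value_counts())
        fractions = sorted(reg.extant.values())
        for size, frac in zip(sizes, fractions):
            sd = np.sqrt(500 * frac * (1 - frac))
            assert abs(size - 500 * frac) <= 3 * sd

    def test_noise_runs_are_short(self):
        truth = syn.simulate_truth(n_clones=2, seed=15)
        cells = syn.render_cells(truth, truth.regions[0].name, n_cells=3,
                                 bin_noise_rate=0.02, seed=2)
        assert cells.shape == (3, 22 * 100)
        assert (cells.to_numpy() >= 0).all()
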