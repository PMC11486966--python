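# clonecarto

Subclone reconstruction, phylogenetics and spatial mapping for copy-number
driven tumors sampled across multiple regions and timepoints.

Neuroblastoma and similar embryonal cancers evolve mostly through chromosomal
copy-number aberrations (CNAs), which violate the infinite-sites assumptions
behind standard phylogenetic tooling: whole-chromosome changes recur in
parallel, gains can revert, and only breakpoints and lost heterozygosity are
(nearly) irreversible. `clonecarto` implements a reconstruction pipeline for
this regime, aimed at researchers analyzing multi-region SNP-array +
sequencing data from clinical tumors, xenografts, cell lines, or shallow
single-cell WGS.

## What it computes

**Clone sizes.** A segment's linear copy ratio `R` relative to reference
ploidy `Np` follows the dosage model

    R = (MSF·Nt + (1 − MSF)·Nb) / Np

where the mutated sample fraction MSF is the portion of all cells carrying
the aberration, `Nt` its total allele count, and `Nb` the background count.
The mirrored B-allele frequency (mBAF ≥ 0.5) gives an independent estimate:

    MSF = (1 − 2·mBAF) / (mBAF·(NA + NB − 2) − NB + 1)

Purity (tumor cell fraction, TCF) is the median MSF of clonal aberrations,
cross-checked between the two readouts; MCF = MSF / TCF is the fraction of
*tumor* cells carrying the event. Sequencing variants enter via

    MCF = VAF·(CN1·f1 + CN2·(TCF − f1) + 2(1 − TCF)) / (M·TCF)

with multiplicity `M` chosen by explicit rules (no clone above 120%, no
impossible event order, no pigeonhole violation, fewest novel subclones).

**Deconvolution.** Events with the same MCF pattern across samples belong to
one subclone; complete-linkage clustering under a per-sample tolerance
recovers the groups, and nesting is resolved under two hard constraints:
parallel subclones cannot exceed 100% of any biopsy (pigeonhole), and a
nested clone can never exceed its mother. Same-segment events with different
allelic compositions ("mixed") are barred from nesting.

**Phylogeny and statistics.** The binary subclone-by-event matrix yields a
maximum-parsimony tree rooted in a zero-alteration cell (conflict-free
matrices take the exact perfect-phylogeny route). The index of genomic
diversity of one sample type's subclones is

    IGD = Σᵢ d(MRCA, cloneᵢ) / Σᵢ d(root, cloneᵢ)  ∈ [0, 1],

irregularity is the variance of root-to-clone distances, and the temporal
pattern is classified as **collateral clonal replacement** (later populations
descend from a different most recent ancestor while earlier dominant lineages
disappear) versus **linear evolution** (an ancestor of later-dominant clones
was already detected earlier).

Additional modules call CNA events from single-cell 1 Mb-bin profiles (5-bin
run filter; 2-bin exception for designated high-grade amplicons such as the
*MYCN* region in 2p24), reconstruct approximate 2D subclone territories from
biopsy layouts, and provide exact two-tailed Fisher and Mann–Whitney tests.
A seeded synthetic-tumor generator produces ground-truth clone trees with
bulk and single-cell readouts so every stage is testable end to end.

## Worked example

Simulate a tumor whose dominant lineage is eradicated by treatment while a
collateral branch survives, render noisy bulk readouts (depth 200, ratio
noise 0.05), and run the full reconstruction:

```python
from clonecarto import synthetic_data as syn, stats
from clonecarto.pipeline import PipelineConfig, run_pipeline

scenario = syn.treatment_scenario("ccr", seed=11)
segments, variants = syn.render_bulk_all(scenario.truth, depth=200,
                                         noise_sd=0.05, seed=12)
timepoints = {r.name: r.timepoint for r in scenario.truth.regions}
report = run_pipeline(PipelineConfig(segments=segments, variants=variants,
                                     sample_timepoints=timepoints))

print(report["newick"])
print(report["stats"]["igd"], report["classification"]["pattern"])
```

Output:

```
(((G1:3)G4:5,(G2:4)G5:1)G3:5)root;
{'post': 0.25, 'pre': 0.13} CCR
```

The tree shows the truncal group `G3` (5 events) splitting into the
pre-treatment lineage (`G5` → `G2`) and the collateral post-treatment lineage
(`G4` → `G1`). Genomic diversity is higher after treatment (IGD 0.25 vs
0.13), and the call is `CCR`: none of the populations dominating after
treatment descends from a clone detected before it. The same run estimates
per-sample purity (e.g. `Pre1: 0.87`) and reports 18 events in 5 subclones
with every filter decision tagged in `report["filter_log"]`.

The exact two-tailed Fisher test reproduces the region-unique-subclone
comparison of 9/9 treated versus 2/9 untreated tumors:

```python
>>> round(stats.fisher_exact_two_tailed([[9, 0], [2, 7]]), 4)
0.0023
```

A `clonecarto` command-line tool wraps the same functionality
(`simulate`, `quantify`, `deconvolve`, `tree`, `metrics`, `scwgs`,
`territories`, `run`); see `clonecarto --help`.

## Documentation

`docs/methods.md` describes the models, default parameters, numerical
choices, what the synthetic generator does and does not emulate, and known
limitations.
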