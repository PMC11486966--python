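# Methods

## Scope and model

`clonecarto` reconstructs the subclonal architecture of copy-number driven
tumors from multi-region, multi-timepoint bulk measurements (allele-specific
copy-number segments plus sequencing variants) and from shallow single-cell
WGS copy-number profiles. The underlying population model is a rooted clone
tree: a zero-alteration founder cell acquires genetic events along branches;
every extant clone carries all events on its root path; in each sample the
extant clone fractions over the tumor compartment sum to one, and the
fraction of cells carrying an event (its mutated clone fraction, MCF) is the
cumulative fraction of the subtree below the branch where it arose.

## Clone-size estimation

Two readouts measure the mutated *sample* fraction (MSF) of a segment:

* **Dosage.** The linear copy ratio relative to reference ploidy `Np` is
  `R = (MSF·Nt + (1−MSF)·Nb)/Np`; inverted,
  `MSF = (Np·R − Nb)/(Nt − Nb)`. `Nb` defaults to the reference-ploidy split
  (1+1 for diploid) and may be overridden for parallel-clone backgrounds.
  Array platforms that compress log2 ratios are handled by a correction
  factor in [0.53, 0.60] (default 0.55, the midpoint):
  `R = 2^(log2_observed / factor)`.
* **Allelic imbalance.** With a 1+1 normal background, the mirrored BAF obeys
  `mBAF = (NB·MSF + (1−MSF)) / ((NA+NB)·MSF + 2(1−MSF))`; inverted,
  `MSF = (1 − 2·mBAF)/(mBAF·(NA+NB−2) − NB + 1)`. Copy-number-neutral events
  (e.g. 2+0) are invisible to dosage and rely on this readout alone.

When both readouts exist they are combined by inverse squared sensitivity
(`|dMSF/dreading|`): for a 1+2 trisomy the imbalance readout is ~4× less
sensitive and contributes little, while for losses both carry similar weight.
This is a pure variance-minimizing combination of two estimates of the same
quantity; the noise-free values are unchanged by it.

Purity (TCF) is estimated per sample as the median MSF of clonal
aberrations, separately from each readout; a difference below 0.1 between
the medians flags a consistent ploidy/composition assessment, and their mean
is the consensus. MCF = MSF/TCF. Values in (1.0, 1.2] are rounded down to
1.0 (the tolerated error band of two concomitant ±10% estimates); values
above 1.2 trigger multiplicity re-evaluation.

Variant MCFs follow
`MCF = VAF·(CN1·f1 + CN2·(TCF−f1) + 2(1−TCF)) / (M·TCF)`, reducing to
`VAF·CN/M` for pure material (xenografts, cell lines). The multiplicity `M`
starts at the ploidy default (1 diploid / 2 tetraploid) and is raised when
the majority of carrying samples would exceed an MCF of 1.2. On mixed
copy-number backgrounds the admissible effective multiplicities are
enumerated from order-of-events scenarios: a truncal mutation on the
haplotype whose fate is consistent across the coexisting fractions
(contributing the fraction-weighted sum of the major or of the minor allele
counts), or a mutation private to the largest fraction (one copy, or all
copies of a duplicated allele if acquired before the duplication). Scenarios
private to the minor fraction would imply additional subclones and are not
enumerated — consistent with the selection rule that, among candidates
passing the hard checks (MCF ≤ 1.2 in most samples, no re-gain of a
nullisomic allele, no pigeonhole violation, one event order patient-wide),
the value introducing the fewest novel subclones wins, ties going to the
larger multiplicity.

Variant filters (per patient): < 10 supporting reads (per record); VAF below
the source cutoff in every sample (0.1 default, 0.2 for FFPE exomes, with a
per-patient override down to 0.1 for mutation-poor cases); > 1% of reads in
the matched normal; targeted panels additionally require ≥ 100 reads in at
least one sample. Shared variants at VAF < 0.20 in a sample fixed by a
clonal sweep of a different lineage are treated as technical artifacts.

## Deconvolution

Events are clustered by their MCF pattern across samples with
complete-linkage under the per-sample Chebyshev metric at tolerance
`tol = 0.15` (default; it covers the ~10% clone-size error margin of array
data plus rounding). Group profiles are per-sample means rounded to the
nearest 0.1 (the reporting resolution); the unrounded means are retained for
detection decisions, where rounding bias matters. Pairs of same-coordinate
events with different allelic compositions are never co-clustered and never
nested.

The configuration search inserts groups by decreasing total fraction, each
under the deepest already-placed group that dominates its profile within a
containment tolerance of 0.1, backtracking when the per-sample maximum-weight
antichain (computed exactly by tree dynamic programming) exceeds 1 + 0.1 or
when a pigeonhole-forced pair (fractions summing above 100% somewhere) is not
ancestor-related. Ties in the nesting direction go to the larger summed
fraction, then lexicographic order; the search is exact up to a backtracking
budget. With noisy estimates the strict system can become infeasible, because
single outlier events split off as unplaceable singleton groups; the pipeline
then escalates deterministically — wider containment and antichain
tolerances, must-nest pairs demoted to soft preferences, and finally coarser
grouping tolerances that re-merge the fragments. Every relaxation is logged.
After resolution, nested groups whose unrounded profiles differ by at most
`tol` in every sample are folded together: the "extant" mass separating them
is a subtraction artifact of fragmentation, not an ascertained population.

Pure-material (PDX/cell line) deconvolution sets purity to 1 and `Np = 2`,
calls MCF ≥ 0.9 clonal, rounds clone sizes to the nearest 10%, allows
parallel sums up to 120% before renormalizing to 100%, orders a 2+0 segment
against mostly-trisomic siblings as an allele loss from the trisomy, and
annotates aberrations private to one lineage/tumor versus shared.
Amplifications and homozygous deletions are always scored clonal. Missing
events are inferred patient-wide: same-breakpoint gains with different
allele counts imply the lowest state as stem; whole-chromosome events that
cannot follow a single order are split into inferred-private parallel
events.

## Phylogeny

Each subclone's row in the binary event matrix carries all events on its
root path. Conflict-free matrices (pairwise nested-or-disjoint carrier sets)
yield the unique perfect phylogeny. Otherwise a parsimony search runs —
exhaustive over all topologies up to 7 taxa, stepwise addition with
nearest-neighbor-interchange refinement beyond (the exhaustive bound is kept
low because topology counts explode combinatorially; all noise-free inputs
are conflict-free and never reach the search). Characters default to free
binary (gains and losses both cost 1, permitting the parallel evolution and
back-mutation of whole-chromosome changes); optional classes constrain
breakpoints/SNVs to a single gain without loss and LOH to irreversibility,
and a matrix violating its constraints on every topology is an error. Ties
between equally parsimonious trees are broken toward fewer back mutations,
then the lexicographically smallest Newick string.

Statistics: `IGD = Σ d(MRCA, cloneᵢ) / Σ d(root, cloneᵢ)` over the subclones
detected for one sample type (0 when all coincide with their common node, 1
when that node is the root); irregularity is the sample variance (n−1) of
root-to-taxon distances; total branch length counts all event acquisitions.

**Temporal classification.** A population is *detected* at a timepoint when
its mean extant fraction over that timepoint's samples reaches the detection
limit (default 0.1, the reporting resolution); witnesses for ancestral
claims must clear twice the limit, since asserting that an ancestral
population was ascertained requires more than a borderline signal. A
subclone dominating the latest timepoint is linearly derived if a witness
detected earlier lies on its root path strictly below the patient MRCA — the
common ancestor of everything is trivially ancestral and only counts if it
itself dominated the earlier timepoint. All dominants supported → linear;
none → collateral clonal replacement; otherwise mixed.

## Single-cell WGS

Integer copy numbers over 1 Mb bins are segmented into maximal
constant-value runs deviating from the baseline ploidy (default 2). Runs
shorter than 5 bins are excluded, except high-grade amplifications (copy
number ≥ 5) overlapping a designated amplicon region with ≥ 2 bins; the
defaults are the 2p24 (*MYCN*) and 4q28.3–q31.1 (*MAML3*) windows and are
configurable. Harmonization snaps same-class boundaries agreeing within ±1
bin (the binning granularity) and decomposes overlaps into atomic catalog
intervals, so each cell's event is a union of catalog entries; boundary
disagreements beyond the tolerance are kept as separate entries rather than
silently merged. Cells with identical profiles collapse into counted clone
taxa before tree building. The proportion of progeny (PoP) of a branch
predicate is the fraction of sequenced cells descending from any matching
branch (the root's empty event set counts as a branch, so an
always-true predicate gives 1); predicates keyed on first-generation
branches partition the cells and their PoPs sum to 1. Clone dynamics tables
report per-timepoint genotype fractions over a shared catalog.

## Spatial reconstruction

Biopsies are modeled as discs at known centroids with known areas. A
subclone present in several biopsies sits at the mean of their centroids; a
nested single-sample subclone at its mother's centroid; a private subclone
at half the biopsy radius pointing away from the placed mass, with
subsequent privates fanned out by golden-angle steps — all directions are
defined relative to the data, making the summary statistics (subclones per
mm², median pairwise centroid distance) invariant under rigid
transformations of the layout. Territory areas are fraction × biopsy area,
summed over the biopsies of presence and capped at the available area.
Territories are rendered as circles; only count, area and centroid feed the
statistics.

## Exact tests

The two-sided Fisher exact p value sums the hypergeometric probabilities of
all tables with the observed margins whose point probability does not exceed
the observed one (+1e-12 tolerance); degenerate margins give p = 1. The
Mann–Whitney test enumerates all group assignments for combined n ≤ 20
(midranks handle ties exactly; two-sided p = 2·min(P(U≤u), P(U≥u)) capped at
1) and uses the tie-corrected normal approximation with continuity
correction above. Bonferroni and Benjamini–Hochberg corrections are offered
but never applied by default.

## Synthetic data generator

The generator defines the conditions under which the pipeline is validated.
Defaults: a 22-chromosome genome of 100 × 1 Mb bins; a stem branch always
carrying two trisomies, one monosomy and one copy-neutral imbalance (so
purity is estimable from both readouts in every sample); other branches carry
1 + Poisson(0.5) CNAs (gain/loss/copy-neutral at 0.5/0.35/0.15) and
Poisson(2) SNVs at multiplicity 1 on diploid background — a few events per
clone, on the scale of the hundreds of variants a multi-region patient
analysis yields. CNAs occupy disjoint genomic slots (5–40 bins), so mixed
backgrounds do not arise in simulated data. Region purities are uniform in
[0.6, 0.95]. Segment ratios and mBAFs receive Gaussian noise (default sd
0.05); variant reads are binomial at fixed depth (default 200), roughly a
scaled-down version of deep targeted panels.

Extant clone fractions per region are drawn on the 0.1 grid and
rejection-sampled until the configuration is *identifiable*: every pair of
clones' cumulative profiles is separated by ≥ 0.2 in some sample, and no
clone's profile is dominated (within the nesting tolerance) by a
non-ancestor. Two proposal distributions alternate — free random subsets per
region (so clones span several biopsies, as about a third of real subclones
do) and a home-region partition that remains feasible when clones are many.
This models the premise of the study design: multi-region sampling is what
makes nesting decidable from fractions at all. At three regions the grid
saturates around nine clones; configurations of ten or more clones generally
cannot be packed and the generator reports that rather than emitting an
ambiguous truth. Treatment applies per-clone survival weights with
renormalization and re-quantization; the scenario constructors guarantee by
design that the eradicated lineage held all detectable pre-treatment mass
(collateral replacement) or that a dominant detected ancestor's descendants
expand (linear), with all scenario-critical clones at a mean extant fraction
≥ 0.2 at their timepoint. Single-cell profiles draw cells multinomially from
the extant fractions and flip isolated bins at a configurable noise rate —
exactly the sub-threshold deviations the 5-bin filter must remove.

What the generator does *not* emulate: overlapping CNAs and the mixed
copy-number backgrounds they create (the multiplicity enumeration is tested
directly instead), subclonal whole-genome doubling, FFPE artifact spectra,
mouse-read contamination, spatial autocorrelation of clone fractions between
adjacent biopsies, and sequencing depth variation along the genome. Passing
recovery tests therefore demonstrates correctness of the inference under the
stated noise model, not robustness to every artifact of archival material.

## Numerical choices and determinism

Half-away-from-zero rounding to the 0.1 grid (no banker's ties); clone-size
clamping band [0, 1.2]; consensus purity as the arithmetic mean of the two
medians; sample (n−1) variance for irregularity; all random draws through
seeded NumPy generators, with per-region sub-seeds derived deterministically;
configuration search, tree search, grouping and placement all have
deterministic tie-breaks, so identical inputs and seeds give byte-identical
reports.

## Known limitations

* Nine-plus clones at three regions exceed what 0.1-grid fractions can make
  identifiable; more regions are needed for larger clone counts.
* The temporal classifier is conservative when the only population detected
  early is the patient MRCA itself and it was not dominant.
* The parsimony search beyond 7 taxa is heuristic (stepwise + NNI) for
  conflicting matrices; conflict-free matrices of any size are exact.
* Variant multiplicity handling in the pipeline covers the diploid default
  and the majority-above-1.2 escalation; full mixed-background enumeration is
  exposed as library functions but not wired into the automatic pipeline.
* Territory reconstruction is schematic (circles, greedy placement); it
  supports the density and dispersion statistics, not histology-registered
  maps.
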