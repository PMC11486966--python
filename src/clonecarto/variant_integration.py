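"""Sequencing-variant filtering and VAF -> clone-size conversion.

The variant allele frequency observed in a bulk sample is a function of the
mutated sample fraction, the number of mutated allele copies M, the local
total copy number of the tumor fraction(s) and the normal-cell admixture:

    VAF = M * MSF / (CN1 * f1 + CN2 * f2 + 2 * (1 - TCF))

with ``f1 + f2 = TCF``. Rearranged, the mutated clone fraction is

    MCF = VAF * (CN1 * f1 + CN2 * (TCF - f1) + 2 * (1 - TCF)) / (M * TCF)

which for a pure tumor sample (xenograft, cell line; f1 = TCF = 1, f2 = 0)
reduces to ``MCF = VAF * CN / M``.

The multiplicity M is usually 1 (2 in tetraploid samples) but becomes
ambiguous for mutations sitting on subclonal or mixed copy-number
backgrounds; :func:`enumerate_multiplicities` lists the admissible effective
values and :func:`choose_multiplicity` applies the selection rules (no clone
size above 1.2, no impossible event order, no pigeonhole violation,
consistent order across samples, then fewest novel subclones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .cna_quantification import MCF, FRACTION_CEILING
from .errors import (ConfigurationError, PurityError, UnresolvableMultiplicityError,
                     ValidationError)

VARIANT_SOURCES = ("wes_ffpe", "wes_frozen", "targeted", "pdx_wes")

#: default per-source VAF cutoffs; a variant below its cutoff in *every*
#: sample of the patient is excluded. FFPE exomes use the stricter 0.2.
DEFAULT_VAF_CUTOFFS = {
    "wes_ffpe": 0.2,
    "wes_frozen": 0.1,
    "targeted": 0.1,
    "pdx_wes": 0.1,
}

#: MCF above which a PDX exome variant is considered clonal; lowered to 0.6
#: for shared variants on balanced 1+1 segments clonal in >=90% of carriers.
CLONALITY_MCF = 0.7
CLONALITY_MCF_SHARED_BALANCED = 0.6
SWEEP_VAF_THRESHOLD = 0.20


@dataclass
class VariantCall:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float
    normal_fraction: float = 0.0
    source: str = "wes_frozen"
    gene: Optional[str] = None
    mcf: Optional[float] = None
    m: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"VAF must lie in [0, 1], got {self.vaf}")
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"alt reads {self.alt_reads} exceed depth {self.depth}")
        if self.m <= 0:
            raise ValidationError(f"multiplicity must be positive, got {self.m}")
        if self.source not in VARIANT_SOURCES:
            raise ConfigurationError(f"unknown variant source {self.source!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CopyNumberContext:
    """Local copy-number composition of the sample at a variant position."""

    cn1: float
    f1: float
    tcf: float
    cn2: Optional[float] = None
    f2: float = 0.0

    def __post_init__(self):
        if self.f1 < 0 or self.f2 < 0 or self.cn1 < 0:
            raise ValidationError("fractions and copy numbers must be non-negative")
        if abs((self.f1 + self.f2) - self.tcf) > 1e-9:
            raise ValidationError(
                f"f1 + f2 = {self.f1 + self.f2} must equal the purity {self.tcf}")
        if self.f2 > 0 and self.cn2 is None:
            raise ValidationError("a background fraction f2 > 0 requires cn2")


@dataclass
class FilterPolicy:
    min_alt_reads: int = 10
    max_normal_fraction: float = 0.01
    vaf_cutoffs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VAF_CUTOFFS))
    targeted_min_depth: int = 100

    def cutoff(self, source: str) -> float:
        try:
            return self.vaf_cutoffs[source]
        except KeyError:
            raise ConfigurationError(f"no VAF cutoff configured for source {source!r}")


@dataclass
class FilterResult:
    kept: list[VariantCall]
    rejected: list[tuple[VariantCall, str]]

    @property
    def rejection_reasons(self) -> dict[tuple, str]:
        return {(v.sample_id,) + v.key: reason for v, reason in self.rejected}


def filter_variants(variants: Iterable[VariantCall],
                    policy: Optional[FilterPolicy] = None) -> FilterResult:
    """Partition a patient's variant records into kept and rejected.

    Record-level rule: fewer than ``min_alt_reads`` supporting reads.
    Variant-level rules (applied to all records of a variant jointly): VAF
    below the source-specific cutoff in every sample; more than 1% of reads
    in the matched normal in any sample; for targeted panels, fewer than 100
    total reads in every sample. Each rejection carries its rule tag, and the
    filter is idempotent.
    """
    policy = policy or FilterPolicy()
    variants = list(variants)
    kept: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []

    by_key: dict[tuple, list[VariantCall]] = {}
    for v in variants:
        by_key.setdefault(v.key, []).append(v)

    variant_reason: dict[tuple, str] = {}
    for key, records in by_key.items():
        if any(r.normal_fraction > policy.max_normal_fraction for r in records):
            variant_reason[key] = "normal_contamination"
        elif all(r.vaf < policy.cutoff(r.source) for r in records):
            variant_reason[key] = "vaf_below_cutoff_all_samples"
        else:
            targeted = [r for r in records if r.source == "targeted"]
            if targeted and all(r.depth < policy.targeted_min_depth for r in records):
                variant_reason[key] = "low_coverage_all_samples"

    for v in variants:
        if v.alt_reads < policy.min_alt_reads:
            rejected.append((v, "min_reads"))
        elif v.key in variant_reason:
            rejected.append((v, variant_reason[v.key]))
        else:
            kept.append(v)
    return FilterResult(kept=kept, rejected=rejected)


def mcf_from_vaf(vaf: float, m: float, ctx: CopyNumberContext) -> MCF:
    """Mutated clone fraction from a VAF given the copy-number context."""
    if ctx.tcf <= 0:
        raise PurityError("tumor cell fraction must be positive")
    if m <= 0:
        raise ValidationError(f"multiplicity must be positive, got {m}")
    cn2 = ctx.cn2 if ctx.cn2 is not None else 0.0
    numerator = vaf * (ctx.cn1 * ctx.f1 + cn2 * (ctx.tcf - ctx.f1) + 2.0 * (1.0 - ctx.tcf))
    raw = numerator / (m * ctx.tcf)
    return _clamp_mcf(raw)


def mcf_from_vaf_pure(vaf: float, cn: float, m: float) -> MCF:
    """Clone fraction in a pure tumor sample (xenograft or cell line)."""
    if cn == 0:
        raise ValidationError("a variant cannot reside on a homozygously deleted segment")
    if m <= 0:
        raise ValidationError(f"multiplicity must be positive, got {m}")
    return _clamp_mcf(vaf * cn / m)


def _clamp_mcf(raw: float) -> MCF:
    if raw > FRACTION_CEILING:
        return MCF(1.0, raw, clamped=True, review_multiplicity=True)
    if raw > 1.0:
        return MCF(1.0, raw, clamped=True)
    return MCF(max(raw, 0.0), raw)


def default_multiplicity(ploidy: int) -> int:
    """Starting multiplicity: 1 in diploid, 2 in tetraploid samples."""
    return 2 if ploidy >= 4 else 1


def enumerate_multiplicities(
        composition: Optional[tuple[int, int]] = None,
        mix: Optional[Sequence[tuple[tuple[int, int], float]]] = None,
        ploidy: int = 2) -> list[float]:
    """Admissible effective multiplicities for a variant.

    On a single copy-number background ``(n_a, n_b)`` the mutation may sit on
    1 up to ``n_a + n_b`` copies, so the integer candidates ``1..n_a+n_b`` are
    returned. Without any composition, the ploidy default applies.

    On a *mixed* background — two subclonal compositions with fractions
    ``f_i`` — the effective multiplicity depends on the order of events.
    Admissible scenarios are (i) a truncal mutation on the haplotype with a
    consistent fate across the fractions, contributing the fraction-weighted
    sum of either the major or the minor allele counts, and (ii) a mutation
    private to the largest fraction, on one copy or (if acquired before that
    allele's duplication) on all copies of the duplicated allele. Scenarios
    private to the minor fraction would introduce additional subclones and
    are not enumerated.
    """
    if mix:
        if len(mix) != 2:
            raise ConfigurationError("a mixed background consists of exactly two compositions")
        candidates: set[float] = set()
        # truncal: mutated haplotype consistently the major / the minor allele
        candidates.add(sum(max(a, b) * f for (a, b), f in mix))
        candidates.add(sum(min(a, b) * f for (a, b), f in mix))
        # private to the largest fraction
        (a, b), f = max(mix, key=lambda item: item[1])
        candidates.add(1.0 * f)
        if max(a, b) >= 2:
            candidates.add(float(max(a, b)) * f)
        candidates.discard(0.0)
        return sorted(round(c, 10) for c in candidates)
    if composition is not None:
        a, b = composition
        total = a + b
        if total < 1:
            raise ValidationError("a variant cannot reside on a homozygous deletion")
        return [float(m) for m in range(1, total + 1)]
    return [float(default_multiplicity(ploidy))]


def choose_multiplicity(
        candidates: Sequence[float],
        trial_mcfs: Mapping[float, Sequence[float]],
        impossible_order: Iterable[float] = (),
        pigeonhole_violations: Iterable[float] = (),
        order_inconsistent: Iterable[float] = (),
        novel_subclones: Optional[Mapping[float, int]] = None) -> float:
    """Select the multiplicity according to the ordered rule set.

    1. reject candidates whose MCF exceeds 1.2 in the majority of carrying
       samples (a higher multiplicity is then preferred);
    2. reject biologically impossible event orders (a nullisomic allele
       cannot be re-gained) — supplied by the caller as ``impossible_order``;
    3. reject candidates violating the pigeonhole principle;
    4. reject candidates implying a different CNA/SNV order across samples
       sharing the aberrations.

    Among the survivors the candidate introducing the fewest novel subclones
    wins; exact ties go to the larger multiplicity (fewer implied mutated
    cells, conservative on heterogeneity).
    """
    if not candidates:
        raise UnresolvableMultiplicityError("no candidate multiplicities supplied")
    rejected: dict[float, str] = {}
    survivors = []
    impossible = set(impossible_order)
    pigeonhole = set(pigeonhole_violations)
    inconsistent = set(order_inconsistent)
    for m in candidates:
        mcfs = trial_mcfs.get(m, ())
        if mcfs and sum(1 for x in mcfs if x > FRACTION_CEILING) * 2 > len(mcfs):
            rejected[m] = "mcf_above_1.2_in_majority"
        elif m in impossible:
            rejected[m] = "impossible_event_order"
        elif m in pigeonhole:
            rejected[m] = "pigeonhole_violation"
        elif m in inconsistent:
            rejected[m] = "inconsistent_order_across_samples"
        else:
            survivors.append(m)
    if not survivors:
        raise UnresolvableMultiplicityError(
            f"all candidates rejected: { {m: why for m, why in rejected.items()} }")
    if novel_subclones:
        best = min(novel_subclones.get(m, 0) for m in survivors)
        survivors = [m for m in survivors if novel_subclones.get(m, 0) == best]
    return max(survivors)


def is_clonal(mcf: float, shared_balanced: bool = False) -> bool:
    """Clonality call for pure-sample (PDX/cell line) exome variants.

    Monotone in MCF; the threshold drops from 0.7 to 0.6 for variants on
    shared balanced 1+1 segments that are clonal in >=90% of carriers.
    """
    threshold = CLONALITY_MCF_SHARED_BALANCED if shared_balanced else CLONALITY_MCF
    return mcf > threshold


def sweep_artifact_filter(vaf: float, shared: bool, swept_sample: bool,
                          threshold: float = SWEEP_VAF_THRESHOLD) -> bool:
    """Keep/drop decision for a variant record under the clonal-sweep rule.

    A *shared* variant detected at low frequency (VAF < 0.20) in a sample
    where a clonal sweep has fixed a different lineage is a technical
    artifact; returns False (drop) in exactly that case.
    """
    return not (shared and swept_sample and vaf < threshold)
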