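"""Clone-size estimation from allele-specific copy-number readouts.

An SNP-array segment yields two largely independent measurements of the
mutated sample fraction (MSF) — the portion of *all* cells in a sample,
normal cells included, that carry an aberration:

* the linear total-copy ratio ``R`` relative to the reference ploidy ``Np``,

      R = (MSF * Nt + (1 - MSF) * Nb) / Np

  where ``Nt`` is the total allele count of the aberrant cells and ``Nb`` the
  allele count of the background cells (a parallel clone, or simply the
  sample ploidy);

* the mirrored B-allele frequency (mBAF), the major-allele fraction >= 0.5,
  which for a normal-cell background of one A and one B allele satisfies

      mBAF = (NB * MSF + (1 - MSF)) / ((NA + NB) * MSF + 2 * (1 - MSF)).

Both relations are inverted here. Dividing MSF by the sample's tumor cell
fraction (TCF, i.e. purity) converts it into the mutated clone fraction
(MCF), the portion of *tumor* cells carrying the aberration, the quantity on
which all downstream deconvolution operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, NamedTuple, Optional

from .errors import ConfigurationError, NoSignalError, PurityError, ValidationError

#: clone-size values above this are considered measurement artifacts that
#: require re-evaluation (e.g. of the mutation multiplicity)
FRACTION_CEILING = 1.2

#: agreement tolerance between ratio-based and imbalance-based purity
TCF_CONSISTENCY_TOL = 0.1

MIN_SEGMENT_LENGTH = 100_000  # bp; shorter segments are excluded upstream


@dataclass
class SegmentCall:
    """One allele-specific copy-number segment in one sample.

    ``n_a <= n_b`` are the allele counts of the aberrant cells (mirrored:
    minor first), ``n_bg_a``/``n_bg_b`` those of the background cells
    (defaults: the reference-ploidy split, 1+1 for diploid).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    ratio: float
    n_a: int
    n_b: int
    mbaf: Optional[float] = None
    ai: Optional[float] = None
    n_bg_a: int = 1
    n_bg_b: int = 1
    msf_ratio: Optional[float] = None
    msf_baf: Optional[float] = None
    mixed_flag: bool = False
    clonal_hint: bool = False
    event_id: Optional[str] = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"segment end {self.end} < start {self.start}")
        if self.end - self.start + 1 < MIN_SEGMENT_LENGTH:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} shorter than "
                f"{MIN_SEGMENT_LENGTH / 1e6:g} Mb")
        if not (0 <= self.n_a <= self.n_b):
            raise ValidationError(f"allele counts must satisfy 0 <= n_a <= n_b, got {self.n_a}+{self.n_b}")
        if self.ratio <= 0:
            raise ValidationError(f"copy ratio must be positive, got {self.ratio}")
        if self.mbaf is not None and not 0.5 <= self.mbaf <= 1.0:
            raise ValidationError(f"mBAF must lie in [0.5, 1], got {self.mbaf}")
        if self.ai is not None and not 0.0 <= self.ai <= 1.0:
            raise ValidationError(f"allelic imbalance must lie in [0, 1], got {self.ai}")
        if self.mbaf is None and self.ai is not None:
            self.mbaf = ai_mbaf_convert(self.ai, "to_mbaf")

    @property
    def nt(self) -> int:
        return self.n_a + self.n_b

    @property
    def nb(self) -> int:
        return self.n_bg_a + self.n_bg_b


@dataclass
class SamplePurity:
    sample_id: str
    tcf_ratio: float
    tcf_ai: float
    tcf: float = field(init=False)
    consistent: bool = field(init=False)

    def __post_init__(self):
        # consensus purity: average of the two median-based estimates
        self.tcf = (self.tcf_ratio + self.tcf_ai) / 2.0
        self.consistent = abs(self.tcf_ratio - self.tcf_ai) < TCF_CONSISTENCY_TOL
        if not 0 < self.tcf <= FRACTION_CEILING:
            raise PurityError(f"tumor cell fraction {self.tcf} outside (0, {FRACTION_CEILING}]")
        self.tcf = min(self.tcf, 1.0)


class MCF(NamedTuple):
    """A mutated clone fraction with its clamping provenance.

    ``value`` is the reported MCF; ``raw`` the unclamped quotient. Values in
    (1.0, 1.2] are rounded down to 1.0 (``clamped``); values above 1.2 are
    flagged for multiplicity re-evaluation (``review_multiplicity``) and
    capped at 1.0 as well.
    """

    value: float
    raw: float
    clamped: bool = False
    review_multiplicity: bool = False


def _clamp_fraction(raw: float) -> float:
    """Clamp a clone-size estimate to the tolerated band [0, 1.2]."""
    return min(max(raw, 0.0), FRACTION_CEILING)


# ---------------------------------------------------------------------------
# forward models (used by the synthetic generator and the round-trip tests)

def ratio_from_msf(msf: float, nt: int, nb: int, np_: int = 2) -> float:
    """Linear total-copy ratio of a segment mutated in a fraction ``msf``."""
    if np_ < 1:
        raise ConfigurationError("reference ploidy must be >= 1")
    return (msf * nt + (1.0 - msf) * nb) / np_


def mbaf_from_msf(msf: float, n_a: int, n_b: int) -> float:
    """Mirrored B-allele frequency of a segment with composition ``n_a + n_b``
    mutated in a sample fraction ``msf`` against a 1+1 normal background."""
    btot = n_b * msf + (1.0 - msf)
    atot = n_a * msf + (1.0 - msf)
    return btot / (atot + btot)


# ---------------------------------------------------------------------------
# inversions

def msf_from_ratio(ratio: float, nt: int, nb: int, np_: int = 2) -> float:
    """Mutated sample fraction from a linear copy ratio.

    Inverts the ratio model; requires a dosage difference between mutated and
    background cells (``nt != nb``).
    """
    if np_ < 1:
        raise ConfigurationError("reference ploidy must be >= 1")
    if ratio <= 0:
        raise ValidationError(f"copy ratio must be positive, got {ratio}")
    if nt == nb:
        raise NoSignalError(
            f"composition {nt} equals background {nb}: segment carries no dosage signal")
    return _clamp_fraction((np_ * ratio - nb) / (nt - nb))


def msf_from_mbaf(mbaf: float, n_a: int, n_b: int) -> float:
    """Mutated sample fraction from the mirrored B-allele frequency."""
    if not 0.5 <= mbaf <= 1.0:
        raise ValidationError(f"mBAF must lie in [0.5, 1], got {mbaf}")
    if n_a == n_b:
        raise NoSignalError(f"balanced composition {n_a}+{n_b} carries no imbalance signal")
    denom = mbaf * (n_a + n_b - 2) - n_b + 1
    if denom == 0:
        raise NoSignalError("degenerate composition: imbalance is independent of clone size")
    return _clamp_fraction((1.0 - 2.0 * mbaf) / denom)


def apply_platform_correction(observed_log2: float, factor: float = 0.55) -> float:
    """Linearize a platform log2 value compressed by a known factor.

    Array platforms report log2 ratios compressed by a factor in the range
    0.53–0.60; the default 0.55 is the midpoint. Returns the linear copy
    ratio ``2 ** (observed_log2 / factor)``. Pass ``factor=1.0`` for
    uncompressed log2 input.
    """
    if factor <= 0:
        raise ConfigurationError(f"compression factor must be positive, got {factor}")
    return 2.0 ** (observed_log2 / factor)


def ai_mbaf_convert(value: float, direction: str) -> float:
    """Convert between allelic imbalance (AI) and mirrored BAF.

    AI = (mBAF - 0.5) / 0.5; the round trip is the identity.
    """
    if direction == "to_ai":
        if not 0.5 <= value <= 1.0:
            raise ValidationError(f"mBAF must lie in [0.5, 1], got {value}")
        return (value - 0.5) / 0.5
    if direction == "to_mbaf":
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"AI must lie in [0, 1], got {value}")
        return 0.5 + 0.5 * value
    raise ConfigurationError(f"direction must be 'to_ai' or 'to_mbaf', got {direction!r}")


def estimate_tcf(segments: Iterable[SegmentCall]) -> SamplePurity:
    """Sample purity from the segments judged clonal.

    The ratio-based and imbalance-based MSFs of clonal aberrations each
    estimate the tumor cell fraction; their medians are compared (a
    difference below 0.1 indicates a correct ploidy/composition assessment)
    and averaged into the consensus TCF.
    """
    segments = [s for s in segments if s.clonal_hint]
    if not segments:
        raise PurityError("no clonal segments available for purity estimation")
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) != 1:
        raise ValidationError(f"segments from multiple samples: {sorted(sample_ids)}")
    ratio_msfs = [s.msf_ratio for s in segments if s.msf_ratio is not None]
    baf_msfs = [s.msf_baf for s in segments if s.msf_baf is not None]
    if not ratio_msfs or not baf_msfs:
        raise PurityError(
            "purity needs at least one clonal ratio-based and one imbalance-based MSF")
    return SamplePurity(sample_id=sample_ids.pop(),
                        tcf_ratio=float(median(ratio_msfs)),
                        tcf_ai=float(median(baf_msfs)))


def mcf_from_msf(msf: float, tcf: float) -> MCF:
    """Mutated clone fraction MCF = MSF / TCF with the clamping policy.

    Values in (1.0, 1.2] are rounded down to 1.0; values above 1.2 are kept
    at 1.0 but flagged so the caller can re-evaluate the multiplicity or
    allele composition.
    """
    if tcf <= 0:
        raise PurityError(f"tumor cell fraction must be positive, got {tcf}")
    if msf < 0:
        raise ValidationError(f"MSF must be non-negative, got {msf}")
    raw = msf / tcf
    if raw > FRACTION_CEILING:
        return MCF(1.0, raw, clamped=True, review_multiplicity=True)
    if raw > 1.0:
        return MCF(1.0, raw, clamped=True)
    return MCF(raw, raw)


def msf_sensitivities(seg: SegmentCall, np_: int = 2) -> tuple[Optional[float], Optional[float]]:
    """|d MSF / d reading| for the ratio and mBAF readouts of a segment.

    With comparable measurement noise on the two readings, the readout with
    the smaller sensitivity yields the more precise MSF; the inverse squared
    sensitivities serve as combination weights. The ratio sensitivity is the
    constant Np/|Nt-Nb|; the mBAF sensitivity is the derivative of the
    inversion formula at the observed mBAF.
    """
    s_ratio = None
    if seg.nt != seg.nb:
        s_ratio = np_ / abs(seg.nt - seg.nb)
    s_baf = None
    if seg.mbaf is not None and seg.n_a != seg.n_b:
        k = seg.n_a + seg.n_b - 2
        g = seg.mbaf * k - seg.n_b + 1
        if g != 0:
            # d/dx (1-2x)/(kx - nb + 1)
            s_baf = abs((-2.0 * g - k * (1.0 - 2.0 * seg.mbaf)) / (g * g))
    return s_ratio, s_baf


def combined_msf(seg: SegmentCall, np_: int = 2) -> Optional[float]:
    """Inverse-variance-weighted combination of the segment's MSF estimates.

    Both readouts measure the same quantity with noise proportional to their
    sensitivities; weighting by the inverse squared sensitivity minimizes the
    variance of the combination. Falls back to whichever single readout
    exists.
    """
    s_ratio, s_baf = msf_sensitivities(seg, np_)
    estimates, weights = [], []
    if seg.msf_ratio is not None and s_ratio:
        estimates.append(seg.msf_ratio)
        weights.append(1.0 / s_ratio ** 2)
    if seg.msf_baf is not None and s_baf:
        estimates.append(seg.msf_baf)
        weights.append(1.0 / s_baf ** 2)
    if not estimates:
        return seg.msf_ratio if seg.msf_ratio is not None else seg.msf_baf
    return float(sum(e * w for e, w in zip(estimates, weights)) / sum(weights))


def quantify_segment(seg: SegmentCall, np_: int = 2) -> SegmentCall:
    """Fill in the ratio-based and imbalance-based MSFs of a segment in place.

    A balanced-vs-background composition leaves the corresponding readout
    absent rather than raising; a segment with no usable readout at all is a
    validation error.
    """
    if seg.nt != seg.nb:
        seg.msf_ratio = msf_from_ratio(seg.ratio, seg.nt, seg.nb, np_)
    if seg.mbaf is not None and seg.n_a != seg.n_b:
        seg.msf_baf = msf_from_mbaf(seg.mbaf, seg.n_a, seg.n_b)
    if seg.msf_ratio is None and seg.msf_baf is None:
        raise ValidationError(
            f"segment {seg.chrom}:{seg.start}-{seg.end} in {seg.sample_id} has neither "
            "a dosage nor an imbalance signal")
    return seg
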