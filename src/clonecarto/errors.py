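"""Exception hierarchy.

All package errors derive from :class:`CloneCartoError` so callers can catch
one base class; subclasses mirror the distinct failure modes of the pipeline
(validation of inputs, configuration mistakes, signal-free measurements,
purity problems and constraint conflicts during deconvolution).
"""


class CloneCartoError(Exception):
    """Base class for all clonecarto errors."""


class ValidationError(CloneCartoError):
    """Malformed or out-of-range input data."""


class ConfigurationError(CloneCartoError):
    """Invalid parameter or policy configuration."""


class NoSignalError(CloneCartoError):
    """A measurement carries no information about clone size.

    Raised e.g. for a copy-ratio on a segment whose mutated and background
    allele counts coincide, or a balanced allelic composition in the mBAF
    inversion.
    """


class PurityError(CloneCartoError):
    """Tumor cell fraction is unavailable or zero."""


class ConstraintConflictError(CloneCartoError):
    """No subclone configuration satisfies the nesting/pigeonhole constraints."""


class UnresolvableMultiplicityError(CloneCartoError):
    """Every candidate mutation multiplicity was rejected by the selection rules."""


class InfeasibleMatrixError(CloneCartoError):
    """No tree topology is compatible with the event matrix under the
    chromosomal-evolution constraints (e.g. irreversible LOH)."""


class HarmonizationError(CloneCartoError):
    """Single-cell event catalogs of different samples cannot be aligned."""


class NotClassifiableError(CloneCartoError):
    """Temporal evolution cannot be classified (e.g. a single timepoint)."""


class ExtinctionError(CloneCartoError):
    """A treatment scenario killed every clone."""
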