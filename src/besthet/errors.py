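"""Exception hierarchy.

All validation failures raise :class:`BesthetError` subclasses so callers
(and the CLI) can distinguish user-input problems from genuine bugs.
"""


class BesthetError(ValueError):
    """Base class for all package-specific errors."""


class PedigreeError(BesthetError):
    """Invalid pedigree structure."""


class CycleError(PedigreeError):
    """An individual is its own ancestor."""


class DanglingParentError(PedigreeError):
    """A parent id is referenced but never defined."""


class DuplicateIdError(PedigreeError):
    """The same individual id appears more than once."""


class UnknownIndividualError(BesthetError):
    """An id was requested that is not in the pedigree / sample."""


class SexError(PedigreeError):
    """Sex information missing or inconsistent for an X-linked analysis."""


class SingularKinshipError(BesthetError):
    """Kinship matrix is singular or numerically ill-conditioned.

    BLUE weights require an invertible kinship matrix.
    """


class GenotypeError(BesthetError):
    """Malformed genotype data (ploidy mismatch, missing alleles, ...)."""


class WeightError(BesthetError):
    """Weight vector invalid (wrong length or does not sum to one)."""


class DegenerateEstimateError(BesthetError):
    """Estimator undefined for this input (e.g. mean kinship >= 1)."""
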