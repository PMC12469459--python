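"""Exception hierarchy shared across the package."""


class MsatError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(MsatError):
    """Sequence contains characters outside {A, C, G, T}."""


class UndefinedScoreError(MsatError):
    """Region too short for a meaningful cryptic-simplicity score."""


class AnchorTooShortError(MsatError):
    """Flank query below the minimum length for coverage-based anchoring."""


class UnknownTipError(MsatError):
    """A tip state refers to a taxon absent from the tree."""


class DegenerateTreeError(MsatError):
    """Fewer than two tips carry states after pruning."""


class ContractViolationError(MsatError):
    """An operation was called on an input that violates its precondition."""


class InsufficientDataError(MsatError):
    """Too few observations or groups for the requested statistic."""


class MalformedIdError(MsatError):
    """FASTA record id does not follow the species|individual|locus|allele grammar."""


class InvalidRootError(MsatError):
    """Simulator root repeat region cannot be decomposed."""


class NumericalFailureError(MsatError):
    """A numerical integration produced a non-finite result."""
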