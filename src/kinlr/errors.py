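"""Exception hierarchy.

Validation errors (bad input files / parameters) are kept distinct from
computation errors so callers — and the CLI exit codes — can tell them apart.
"""


class KinlrError(Exception):
    """Base class for all package errors."""


class ValidationError(KinlrError):
    """Invalid input data or parameters."""


class ComputationError(KinlrError):
    """A computation could not be carried out on otherwise valid input."""


# -- pedigree -----------------------------------------------------------------

class DuplicateIndividualError(ValidationError):
    """Two rows share the same individual id."""


class DanglingParentError(ValidationError):
    """A parent reference does not resolve to a known individual."""


class PedigreeCycleError(ValidationError):
    """An individual is its own ancestor."""


class ParentSexError(ValidationError):
    """An individual appears in a parent role inconsistent with its sex."""


class UnknownIndividualError(ValidationError):
    """Lookup of an id that is not in the pedigree."""


# -- mtDNA --------------------------------------------------------------------

class MalformedTokenError(ValidationError):
    """A variant token does not follow the POS+BASE / POS.N+BASE / POSDEL grammar."""


class PositionOutOfRangeError(ValidationError):
    """A substitution position lies outside every declared range."""


class DuplicatePositionError(ValidationError):
    """Two substitution tokens share a position."""


class SequenceError(ValidationError):
    """A sequence is malformed (length mismatch, non-IUPAC characters)."""


class NoComparablePositionsError(ComputationError):
    """Two haplotypes declare disjoint ranges: no positions to compare."""


# -- Y-STR --------------------------------------------------------------------

class PanelError(ValidationError):
    """Locus/panel inconsistency in a Y-STR table or comparison."""


class PartitionConfigError(ValidationError):
    """Patriline partitioning was requested without labels or a mismatch cap."""


# -- evidence / config --------------------------------------------------------

class EvidenceConfigError(ValidationError):
    """Malformed evidence configuration."""
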