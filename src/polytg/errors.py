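"""Exception taxonomy for the pipeline.

The two error classes that correspond to reportable clinical failure modes
(tract not detected, no matching genotype) are mapped to report statuses by
:mod:`polytg.report` instead of propagating out of ``run_sample``.
"""


class PolytgError(Exception):
    """Base class for all package errors."""


class NotAbifError(PolytgError):
    """File does not start with the ABIF magic bytes."""


class MissingRecordError(PolytgError):
    """A required ABIF directory record is absent."""

    def __init__(self, tag_name: str, tag_number: int | None = None):
        self.tag_name = tag_name
        self.tag_number = tag_number
        suffix = "" if tag_number is None else str(tag_number)
        super().__init__(f"required ABIF record missing: {tag_name}{suffix}")


class MalformedDirectoryError(PolytgError):
    """ABIF directory entry with out-of-bounds offsets or duplicate tags."""


class IoError(PolytgError):
    """Low-level read/write failure."""


class UninformativePositionError(PolytgError):
    """Signal-presence query on a position masked as uninformative."""


class AnchorNotFoundError(PolytgError):
    """No window matches the flank anchor within the mismatch tolerance."""


class AmbiguousAnchorError(PolytgError):
    """Two or more windows tie at the minimal anchor distance."""


class EmptySpaceError(PolytgError):
    """Genotype search space contains no alleles."""


class DegenerateObservationError(PolytgError):
    """Observed tract windows are empty in both directions."""


class NoMatchingGenotypeError(PolytgError):
    """Every genotype in the search space was eliminated."""


class InvalidSpecError(PolytgError):
    """Simulation specification violates its invariants."""
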