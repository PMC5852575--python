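"""Exception hierarchy for the package.

All package errors derive from :class:`RnaOcclusionError` so callers can
catch the whole family with one clause.
"""


class RnaOcclusionError(Exception):
    """Base class for all errors raised by this package."""


class PDBParseError(RnaOcclusionError):
    """A PDB record could not be parsed; the message names the line."""


class TopologyError(RnaOcclusionError):
    """Models of a multi-model file disagree in atom content or order."""


class CoordinateRangeError(RnaOcclusionError):
    """A coordinate cannot be represented in fixed PDB columns."""


class DegenerateGeometryError(RnaOcclusionError):
    """Point set too small or too degenerate for a rigid-body fit."""


class CorrespondenceError(RnaOcclusionError):
    """Selected atoms of the reference have no counterpart in the ensemble."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class AnnotationError(RnaOcclusionError):
    """A required per-atom annotation (e.g. vdW radius) is missing."""


class InsufficientFramesError(RnaOcclusionError):
    """An operation needs more frames than the ensemble provides."""


class QuantificationError(RnaOcclusionError):
    """A ratio is undefined (zero total peak area or molarity)."""


class SchemaError(RnaOcclusionError):
    """An input table lacks a required column; the message names it."""


class UsageError(RnaOcclusionError):
    """An operation was called in a way its contract forbids."""


class DomainError(ValueError, RnaOcclusionError):
    """A numeric argument is outside its mathematical domain."""
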