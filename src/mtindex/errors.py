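"""Exception hierarchy shared across the package.

All domain errors derive from :class:`MTIndexError`, so callers (and the
CLI) can catch one base class and still report specific failure modes.
"""


class MTIndexError(Exception):
    """Base class for all errors raised by mtindex."""


class FormatError(MTIndexError):
    """A delimited-text file does not follow the expected layout."""


class ScoreParseError(FormatError):
    """A field could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(MTIndexError):
    """Duplicate (compound, target, structure) keys in a score table."""


class ReferenceSelectionError(MTIndexError):
    """No valid (negative-score) reference ligand exists for a target."""


class MissingScoreError(MTIndexError):
    """A compound lacks a score required by the index (strict mode)."""


class NonNegativeScoreError(MTIndexError):
    """A non-negative docking score where affinity credit is required."""


class GeometryError(MTIndexError):
    """Scatter geometry unsuitable for triangulation (too few/collinear)."""


class StructureParseError(MTIndexError):
    """A PDB file could not be parsed."""


class TrajectoryError(MTIndexError):
    """Frames of a multi-model file are structurally inconsistent."""


class SelectionError(MTIndexError):
    """An atom selection matched nothing or the wrong multiplicity."""


class PairingError(MTIndexError):
    """Two coordinate sets cannot be paired atom-by-atom."""


class SuperpositionError(MTIndexError):
    """Degenerate geometry: optimal superposition is not defined."""


class WindowError(MTIndexError):
    """A time-series analysis window contains no frames."""


class ConfigError(MTIndexError):
    """Invalid synthetic-generator or run configuration."""
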