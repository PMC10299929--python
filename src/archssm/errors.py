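"""Exception hierarchy for the arch shape-modeling pipeline.

Every error raised by the library derives from :class:`ArchSSMError`,
so callers (and the CLI) can map error categories to exit codes.
"""


class ArchSSMError(Exception):
    """Base class for all errors raised by archssm."""


class ParameterError(ArchSSMError, ValueError):
    """An input parameter violates its invariant (names the offending field)."""


class LandmarkError(ArchSSMError):
    """A landmark lies outside the mesh or is otherwise unusable."""


class TopologyError(ArchSSMError):
    """No interior path exists between the requested landmarks."""


class ClipError(ArchSSMError):
    """Clipping disconnected the aortic route between seed and target."""


class DecompositionError(ArchSSMError):
    """The two centerlines cannot be merged at a bifurcation origin."""


class SegmentError(ArchSSMError):
    """A decomposed segment is too short to resample."""


class CorrespondenceError(ArchSSMError):
    """Cases do not share identical per-segment point counts."""


class InsufficientDataError(ArchSSMError):
    """Not enough cases (or classes) to fit the requested model."""


class DegeneratePoseError(ArchSSMError):
    """The ductal direction is vertical; the Z-rotation is undefined."""


class AlignmentRequiredError(ArchSSMError):
    """An operation that assumes pose-normalized input received raw geometry."""


class ConditioningError(ArchSSMError):
    """A linear system is singular beyond the ridge rescue."""


class SchemaError(ArchSSMError):
    """A structured input file is missing required keys or fields."""


class ParseError(ArchSSMError):
    """A data file is malformed (carries a line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyMeshError(ArchSSMError):
    """A surface mesh contains no triangles."""
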