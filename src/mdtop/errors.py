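"""Exception hierarchy.

Every error raised by :mod:`mdtop` derives from :class:`MdtopError`, so callers
can catch the whole family with a single clause while tests pin down the exact
failure mode.
"""


class MdtopError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MdtopError, ValueError):
    """A synthetic-data specification violates its invariants."""


class ShapeError(MdtopError, ValueError):
    """Array shapes are inconsistent (e.g. atom-count mismatch)."""


class FormatError(MdtopError, ValueError):
    """A structure file does not parse under the named dialect."""


class UsageError(MdtopError, ValueError):
    """An operation was called with inconsistent arguments."""


class SelectionError(MdtopError, ValueError):
    """An atom selection failed to parse or selected nothing."""


class ProtocolError(MdtopError, RuntimeError):
    """The frame-sampling protocol cannot be satisfied."""


class DegenerateInputError(MdtopError, ValueError):
    """Geometric input is degenerate (too few atoms, collinear, ...)."""


class TopologyError(MdtopError, ValueError):
    """The topology lacks a role required by the operation."""


class BlockedStartError(MdtopError, RuntimeError):
    """Tunnel search: the start point itself has free radius below the probe."""


class PipelineError(MdtopError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
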