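"""Exception hierarchy shared across the toolkit."""


class BCStarPromError(Exception):
    """Base class for all package errors."""


class LengthMismatchError(BCStarPromError, ValueError):
    """Two sequences that must have equal length do not."""


class InvalidPatternError(BCStarPromError, ValueError):
    """A degenerate pattern contains an unrecognized IUPAC code."""


class CapacityError(BCStarPromError, ValueError):
    """More distinct items requested than the combinatorial space holds."""


class InfeasibleDesignError(BCStarPromError, RuntimeError):
    """Randomized search exhausted its attempt budget without a valid design."""


class ValidationError(BCStarPromError, ValueError):
    """An object violates a library-level invariant (e.g. barcode off-pattern)."""


class QCError(BCStarPromError, ValueError):
    """A quality-control gate failed (e.g. zero-median sample column)."""


class ConfigError(BCStarPromError, ValueError):
    """A configuration value is missing, unknown or out of range."""


class TooShortReadError(BCStarPromError, ValueError):
    """A read is too short for the requested trimming window."""


class PipelineOrderError(BCStarPromError, ValueError):
    """An operation received input that an upstream stage should have rejected."""


class StageError(BCStarPromError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
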