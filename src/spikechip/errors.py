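"""Exception hierarchy for the spikechip pipeline."""


class SpikeChipError(Exception):
    """Base class for all spikechip errors."""


class ConfigError(SpikeChipError, ValueError):
    """Invalid configuration or parameter value."""


class MalformedReadError(SpikeChipError, ValueError):
    """A sequencing read violates a structural precondition."""


class PlacementError(SpikeChipError, RuntimeError):
    """Gene placement could not satisfy spacing constraints."""


class DegenerateProfileError(SpikeChipError, ValueError):
    """An enrichment profile has zero total weight."""


class DegenerateLibraryError(SpikeChipError, ValueError):
    """A read-count library is empty or has a degenerate spike proportion."""


class ProvenanceError(SpikeChipError, ValueError):
    """A track was supplied at the wrong scaling stage."""


class IncompatibilityError(SpikeChipError, ValueError):
    """Two tracks or matrices do not share the required geometry."""


class FormatError(SpikeChipError, ValueError):
    """A file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class EmptyMatrixError(SpikeChipError, ValueError):
    """A signal matrix has no usable rows."""


class StageError(SpikeChipError, RuntimeError):
    """A pipeline stage failed; names the stage and sample."""

    def __init__(self, stage: str, sample: str | None = None):
        self.stage = stage
        self.sample = sample
        where = stage if sample is None else f"{stage} [{sample}]"
        super().__init__(f"pipeline stage failed: {where}")
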