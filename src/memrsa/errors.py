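"""Exception hierarchy shared across the pipeline."""


class MemrsaError(Exception):
    """Base class for all package errors."""


class FormatError(MemrsaError):
    """A file is missing required columns or is otherwise malformed."""


class IntegrityError(MemrsaError):
    """A file parses but violates a structural invariant (e.g. duplicate keys)."""


class ShapeError(MemrsaError):
    """Array/volume dimensions are inconsistent with each other."""


class ParameterError(MemrsaError):
    """A configuration or generator parameter is out of its valid range."""


class GenerationError(MemrsaError):
    """The synthetic-data generator could not satisfy its constraints."""


class InsufficientTrialsError(MemrsaError):
    """Too few trials of a required type to run an analysis."""


class VigilanceUndefinedError(MemrsaError):
    """A worker log has no filler events, so vigilance cannot be assessed."""


class PipelineStageError(MemrsaError):
    """A pipeline stage failed; the message names the stage."""
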