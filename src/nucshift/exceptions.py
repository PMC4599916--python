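"""Exception hierarchy for nucshift."""


class NucshiftError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NucshiftError, ValueError):
    """A parameter specification is internally inconsistent."""


class GeometryError(NucshiftError, ValueError):
    """A geometric constraint is violated (cell outside frame, placement failure)."""


class InputError(NucshiftError, ValueError):
    """Invalid data handed to an operation (shape mismatch, empty group, ...)."""


class NormalizationError(NucshiftError, ValueError):
    """Per-image normalization cannot be computed (e.g. zero image mean)."""


class PipelineError(NucshiftError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
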