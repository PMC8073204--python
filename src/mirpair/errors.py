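"""Exception hierarchy.

Every error raised by the package derives from :class:`MirpairError` so
callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class MirpairError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirpairError):
    """Invalid configuration: unknown group label, missing path, bad alpha."""


class ValidationError(MirpairError):
    """Input data violate a documented invariant (e.g. negative dispersion)."""


class NormalizationError(MirpairError):
    """A sample cannot be normalized (missing reference assay, all-zero counts)."""


class EstimationError(MirpairError):
    """A quantity cannot be estimated (e.g. empty control group)."""


class StatisticsError(MirpairError):
    """A statistical routine received an unusable sample (too small, constant)."""


class FormatError(MirpairError):
    """A file does not conform to the expected tabular format."""


class PipelineError(MirpairError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
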