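"""Exception hierarchy.

All errors raised by this package derive from :class:`SnakemapError` so
callers can catch everything with one clause; the pipeline maps subclasses
to exit codes.
"""


class SnakemapError(Exception):
    """Base class for all snakemap errors."""


class ConfigError(SnakemapError, ValueError):
    """An invalid configuration value; the message names the field."""


class SchemaError(SnakemapError, ValueError):
    """Input table missing required columns, values, or referential links."""


class ParameterError(SnakemapError, ValueError):
    """An operation parameter outside its admissible range."""


class RankDeficiencyError(SnakemapError, ValueError):
    """Design matrix is rank deficient; the message names collinear columns."""


class PipelineError(SnakemapError, RuntimeError):
    """A pipeline stage failed.

    Attributes
    ----------
    stage : name of the failed stage.
    code : machine-readable error code (validation, convergence, io, internal).
    """

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code
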