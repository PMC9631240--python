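"""Exception hierarchy shared across the package.

All input/contract failures derive from :class:`MidasError` so the CLI can map
them onto stable exit codes (configuration → 2, validation/parse → 3,
runtime/numerical → 4).
"""


class MidasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MidasError):
    """A pipeline configuration is incomplete or inconsistent."""


class ValidationError(MidasError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A text input (BED/bedGraph/TSV) failed to parse; names the line."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class BoundsError(ValidationError):
    """A coordinate falls outside its chromosome."""


class DegenerateVarianceError(ValidationError):
    """The spread estimate of normalized counts is zero; sigma is undefined."""


class InfeasibleSamplingError(MidasError):
    """The eligible pool is smaller than the requested sample size."""

    def __init__(self, pool_size: int, requested: int):
        self.pool_size = pool_size
        self.requested = requested
        super().__init__(
            f"eligible pool has {pool_size} bins but {requested} were requested"
        )


class NoDataError(MidasError):
    """Every value needed for a summary is missing."""


class GenerationError(MidasError):
    """Synthetic-world construction is infeasible under the given config."""
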