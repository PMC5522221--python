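"""Exception hierarchy shared across the package."""


class ChromexprError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ChromexprError):
    """Invalid configuration value or schema violation."""


class SizingError(ChromexprError):
    """A requested problem size does not fit the available space/data."""


class NormalizationError(ChromexprError):
    """Signal normalization is undefined (e.g. zero total tag count)."""


class DegenerateSampleError(ChromexprError):
    """A sample is too small or too uniform for the requested estimate."""


class CollinearityError(ChromexprError):
    """Design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class AlignmentError(ChromexprError):
    """Gene identifiers or vector lengths do not line up."""


class UndefinedCorrelationError(ChromexprError):
    """Correlation requested on a constant vector."""


class EstimationError(ChromexprError):
    """A statistical estimate could not be computed."""
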