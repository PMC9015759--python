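"""Exception hierarchy shared across the pipeline."""


class OpenExposuresError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OpenExposuresError):
    """A user-supplied configuration (criteria, scheme, simulation spec) is invalid."""


class ValidationError(OpenExposuresError, ValueError):
    """Input data violate a documented precondition."""


class DegenerateInputError(OpenExposuresError):
    """Numeric input too degenerate to fit a binning scheme (e.g. all values identical)."""


class DegenerateTableError(OpenExposuresError):
    """A contingency table cannot support a chi-square test (empty dichotomy side,
    or fewer than two non-zero rows/columns after pruning)."""


class FormatError(OpenExposuresError):
    """A persisted artifact does not match its declared schema."""
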