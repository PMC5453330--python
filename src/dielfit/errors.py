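"""Exception hierarchy shared across the package."""


class DielfitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DielfitError):
    """An invalid parameter in a simulation or run configuration."""


class InsufficientDataError(DielfitError):
    """Too few samples for the requested fit or test."""


class DegenerateDesignError(DielfitError):
    """Design matrix is rank deficient (e.g. all samples at one ZT)."""


class MatrixFormatError(DielfitError):
    """Malformed matrix or sample-sheet file."""


class SampleSheetError(DielfitError):
    """Sample metadata does not cover the matrix columns (or vice versa)."""
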