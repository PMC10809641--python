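"""Exception hierarchy shared across the package.

Exit codes are consumed by the CLI: configuration problems, malformed or
inconsistent data, and model-level failures map to distinct nonzero codes.
"""


class EpiclockError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(EpiclockError):
    """Invalid parameters or config-file contents."""

    exit_code = 2


class DataError(EpiclockError):
    """Malformed, inconsistent, or incomplete input data."""

    exit_code = 3


class ModelError(EpiclockError):
    """Model cannot be fit or applied (degenerate design, missing features)."""

    exit_code = 4


class CalibrationError(EpiclockError):
    """FDR calibration found no usable cutoff (e.g. zero observed segments)."""

    exit_code = 5


class RankingError(EpiclockError):
    """A gene ranking came out empty (no annotated / surviving features)."""

    exit_code = 6
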