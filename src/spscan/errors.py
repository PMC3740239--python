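"""Exception hierarchy.

Two top-level families matter for the CLI: configuration problems
(wrong flags, missing columns) exit with code 2; data problems
(degenerate tables, too few rows) exit with code 3.
"""


class SpscanError(Exception):
    """Base class for all package errors."""


class ConfigError(SpscanError):
    """The run was set up inconsistently (bad mode, missing column, bad flag)."""


class DataError(SpscanError):
    """The input data cannot support the requested analysis."""


class DegenerateMarginError(DataError):
    """A 2x2 table has a zero row or column total; the chi-square test is undefined."""


class InsufficientDataError(DataError):
    """Too few observations for the requested fit."""


class FitError(SpscanError):
    """A numerical fit failed (all mixture starts diverged, EM log-likelihood decreased)."""
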