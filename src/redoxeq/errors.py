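"""Exception hierarchy.

Validation problems (bad inputs, malformed files, bad configuration) are kept
distinct from analysis failures (a structurally valid dataset that cannot be
analysed), so the command-line layer can map them to distinct exit codes.
"""


class RedoxeqError(Exception):
    """Base class for all package errors."""


class ValidationError(RedoxeqError, ValueError):
    """Invalid input data, configuration or arguments."""


class ParseError(ValidationError):
    """A delimited-text file could not be parsed; the message names the cell."""


class AnalysisError(RedoxeqError, RuntimeError):
    """A valid dataset could not be analysed (degenerate or insufficient data)."""


class StabilityError(AnalysisError):
    """A trace never satisfied the spectral stability criterion."""


class InsufficientCoverageError(AnalysisError):
    """Too few titration points survive the fraction-window filter to fit."""
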