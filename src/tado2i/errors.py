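"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`DomainError` (and subclasses)
exit with 3, :class:`ParseError` with 4.
"""


class TaDO2iError(Exception):
    """Base class for all package-specific errors."""


class DomainError(TaDO2iError, ValueError):
    """A physiologically or mathematically invalid input."""


class ParameterError(DomainError):
    """Model or patient parameters outside their allowed ranges."""


class TemperatureRangeError(DomainError):
    """Temperature outside the model validity range without extrapolation."""


class DegenerateDataError(DomainError):
    """Dataset cannot support the requested fit (rank deficiency, too few points)."""


class ParseError(TaDO2iError, ValueError):
    """Malformed input file (CSV/config)."""
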