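"""Exception hierarchy for the memchrom pipeline."""


class MemchromError(Exception):
    """Base class for all package errors."""


class FormatError(MemchromError):
    """Input file does not have the expected layout."""


class CurveValidationError(MemchromError):
    """A breakthrough curve violates a structural invariant."""


class ConfigError(MemchromError):
    """A descriptor or run configuration is missing or malformed."""


class NotReachedError(MemchromError):
    """The curve never crosses the requested breakthrough fraction."""

    def __init__(self, fraction: float, max_c_ratio: float):
        self.fraction = fraction
        self.max_c_ratio = max_c_ratio
        super().__init__(
            f"curve never reaches c_ratio={fraction:g} "
            f"(maximum observed c_ratio={max_c_ratio:g})"
        )


class InsufficientDataError(MemchromError):
    """Too few usable points for the requested regression."""


class FitDegenerateError(MemchromError):
    """The regression produced a physically meaningless parameter sign."""
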