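"""Exception hierarchy for the qkat package."""


class QkatError(Exception):
    """Base class for all qkat errors."""


class PanelError(QkatError):
    """Malformed or internally inconsistent assay-panel fixture."""

    def __init__(self, message, field=None, line=None):
        self.field = field
        self.line = line
        loc = []
        if field is not None:
            loc.append(f"field={field}")
        if line is not None:
            loc.append(f"line={line}")
        super().__init__(message + (f" ({', '.join(loc)})" if loc else ""))


class ValidationError(QkatError):
    """Invalid value passed to a computation."""


class UnsupportedComputation(QkatError):
    """Requested quantity cannot be computed from the available fields."""


class ParseError(QkatError):
    """Instrument export or table file could not be parsed."""


class CalibrationError(QkatError):
    """No usable calibration anchor for a locus on a plate."""


class FitError(QkatError):
    """Log-linear fit through the fit points is undefined."""


class ConfigError(QkatError):
    """Invalid run or simulation configuration."""
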