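"""Exception hierarchy for stemtherm."""


class StemthermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StemthermError):
    """A parameter set or configuration is inconsistent with a model's contract."""


class DegenerateCurveError(StemthermError):
    """A thermal performance curve is identically zero on its domain."""


class InsufficientDataError(StemthermError):
    """Fewer observations than free parameters."""


class SelectionFailureError(StemthermError):
    """No candidate fit survives the selection filters.

    Carries the per-fit discard reasons so callers can report why.
    """

    def __init__(self, message: str, reasons: dict[str, str] | None = None):
        super().__init__(message)
        self.reasons = reasons or {}


class MissingDataError(StemthermError):
    """A temperature ensemble has gaps in its year-month coverage."""


class EmptyWindowError(StemthermError):
    """Development fails at every temperature: no thermal window exists."""
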