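"""Exception hierarchy for the cost-effectiveness model."""


class CeaError(Exception):
    """Base class for all model errors."""


class ValidationError(CeaError, ValueError):
    """An input violates a documented precondition."""


class CalibrationError(CeaError):
    """A survival curve cannot be calibrated from the given evidence."""


class InsufficientDataError(CalibrationError):
    """Too few usable points to fit a parametric curve."""


class StructuralInconsistencyError(CeaError):
    """State-occupancy curves are mutually inconsistent (e.g. PFS above OS)."""


class MissingPriceError(CeaError, KeyError):
    """A configured resource has no unit price for the chosen country."""
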