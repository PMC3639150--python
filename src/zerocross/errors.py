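"""Exception hierarchy.

All package errors derive from :class:`ZeroCrossError` so callers can catch
one base class; each subclass maps to a distinct failure mode of the
measurement workflow.
"""


class ZeroCrossError(Exception):
    """Base class for all zerocross errors."""


class ParseError(ZeroCrossError, ValueError):
    """A file could not be parsed (names the offending row where possible)."""


class GridError(ZeroCrossError, ValueError):
    """Wavelength-grid invariant violated (non-uniform, mismatched, or
    incompatible with a requested delta-lambda)."""


class RangeError(ZeroCrossError, ValueError):
    """A wavelength or interpolation request falls outside the data range."""


class FitError(ZeroCrossError, ValueError):
    """Calibration regression cannot be computed (degenerate design)."""


class QuantificationError(ZeroCrossError, ValueError):
    """Inverse prediction impossible (e.g. zero calibration slope)."""


class SelectionError(ZeroCrossError, ValueError):
    """No usable zero-crossing candidate for wavelength selection."""


class ValidationError(ZeroCrossError, ValueError):
    """Invalid input to a validation-statistics computation."""
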