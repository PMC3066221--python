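"""Exception hierarchy shared across the pipeline stages."""


class ReefcastError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ReefcastError, ValueError):
    """Invalid generator or model parameters."""


class FormatError(ReefcastError, ValueError):
    """Malformed input file (gaps, duplicates, unparseable records)."""


class InsufficientDataError(ReefcastError, ValueError):
    """Too little data to compute the requested statistic."""


class InfeasibleCurveError(ReefcastError, ValueError):
    """Growth-curve anchors cannot support a valid cubic.

    Raised when the temperature of maximum growth falls outside the open
    interval between the two zero-growth temperatures, so no cubic with a
    unit peak between its roots exists.  Carries the anchor values so
    ensemble drivers can log which perturbation draw failed.
    """

    def __init__(self, message: str, anchors: dict | None = None):
        super().__init__(message)
        self.anchors = anchors or {}


class DegenerateInputError(ReefcastError, ValueError):
    """An input whose spread is zero where a nonzero spread is required."""


class ExtrapolationError(ReefcastError, ValueError):
    """A lookup outside the tabulated grid hull; no silent extrapolation."""
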