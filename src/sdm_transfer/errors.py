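"""Exception hierarchy shared across the pipeline stages."""


class SDMTransferError(Exception):
    """Base class for all errors raised by this package."""


class MissingCovariateError(SDMTransferError, KeyError):
    """A required covariate column is absent from the supplied records."""

    def __init__(self, covariate: str, context: str = ""):
        self.covariate = covariate
        msg = f"missing covariate {covariate!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class BasisError(SDMTransferError):
    """Spline basis cannot be built (e.g. too few distinct covariate values)."""


class CalibrationError(SDMTransferError):
    """Intercept calibration failed to bracket the target encounter ratio."""


class ScreeningError(SDMTransferError):
    """Degenerate input to concurvity or univariate-deviance screening."""


class ResamplingError(SDMTransferError):
    """Invalid input to thinning, down-sampling or fold construction."""


class MetricError(SDMTransferError):
    """A validation metric is undefined for the supplied labels or scores."""


class VariogramError(SDMTransferError):
    """Semivariogram cannot be computed (e.g. all points coincident)."""


class ParseError(SDMTransferError):
    """A survey table could not be parsed."""
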