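"""Exception hierarchy shared across the pipeline.

CLI exit-code convention: validation problems map to exit code 2,
fit non-convergence to exit code 3.
"""


class OgbError(Exception):
    """Base class for all ogbkit errors."""


class ValidationError(OgbError, ValueError):
    """A measurement record or argument violates a physical invariant."""


class FormatError(OgbError, ValueError):
    """An input file does not match any of the expected CSV schemas."""


class DegenerateDataError(OgbError, ValueError):
    """Data carry no usable signal (constant series, zero variance)."""


class FitConvergenceError(OgbError, RuntimeError):
    """Nonlinear least squares failed to converge.

    Carries the last parameter iterate (if any) in ``last_params``.
    """

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params
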