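"""Exception hierarchy for csfpk."""


class CsfPkError(Exception):
    """Base class for all csfpk errors."""


class ValidationError(CsfPkError, ValueError):
    """Invalid parameter, dose event, or dataset content."""


class SolverError(CsfPkError, RuntimeError):
    """Simulation failed or produced out-of-tolerance output."""


class FitError(CsfPkError, RuntimeError):
    """Nonlinear fit did not converge or had no usable data."""


class DatasetFormatError(CsfPkError, ValueError):
    """A delimited-text input did not match the expected schema."""


class SteadyStateError(CsfPkError, RuntimeError):
    """Steady state was not reached within the simulated horizon."""


class CalibrationError(CsfPkError, RuntimeError):
    """Standard-curve fitting or inverse calibration failed."""
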