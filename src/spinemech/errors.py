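"""Exception and warning types shared across the package."""


class SpineMechError(Exception):
    """Base class for all spinemech errors."""


class InvalidModelError(SpineMechError, ValueError):
    """A viscoelastic model parameter set violates its invariants."""


class InvalidMeasurementError(SpineMechError, ValueError):
    """A morphometric measurement is non-positive or otherwise impossible."""


class DegenerateInputError(SpineMechError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. zero area)."""


class ProtocolMismatchError(SpineMechError, ValueError):
    """A recording does not match the test protocol the operation assumes."""


class PartialProtocolError(ProtocolMismatchError):
    """The load channel never reached the protocol limits.

    Carries the attained extremes so callers can report how far the test got.
    """

    def __init__(self, message, attained_min=None, attained_max=None):
        super().__init__(message)
        self.attained_min = attained_min
        self.attained_max = attained_max


class CycleOutOfRangeError(SpineMechError, IndexError):
    """Requested cycle index exceeds the number of cycles in the recording."""


class FitFailureError(SpineMechError, RuntimeError):
    """Optimizer failed to converge. Carries the best parameters found so far."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class DesignDegenerateError(SpineMechError, ValueError):
    """Factorial design has an empty or single-observation cell."""


class GeneratorContractError(SpineMechError, ValueError):
    """Synthetic-data protocol and specimen truth are mutually inconsistent."""


class RecordingParseError(SpineMechError, ValueError):
    """A time-series file could not be parsed into a valid recording."""


class PipelineError(SpineMechError, RuntimeError):
    """Batch pipeline failed as a whole (e.g. every specimen errored)."""


class SpineMechWarning(UserWarning):
    """Base class for spinemech warnings."""


class LoopClosureWarning(SpineMechWarning):
    """Hysteresis loop endpoints do not close within tolerance."""


class ProtocolWarning(SpineMechWarning):
    """Recording deviates from the expected protocol in a recoverable way."""


class ExactSeparationWarning(SpineMechWarning):
    """ANOVA residual variance is zero; p values reported as limit values."""


class DesignWarning(SpineMechWarning):
    """Cohort design required truncation/clipping of sampled parameters."""
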