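"""Exception hierarchy for wcdcm."""


class WcdcmError(Exception):
    """Base class for all wcdcm errors."""


class InvalidParameterError(WcdcmError, ValueError):
    """A parameter value violates its domain (e.g. non-positive slope or SNR)."""


class ShapeError(WcdcmError, ValueError):
    """Array dimensions are inconsistent with the model specification."""


class StateDomainError(WcdcmError, ValueError):
    """A hemodynamic state left its physical domain (f, v, q must stay > 0)."""


class DivergenceError(WcdcmError, RuntimeError):
    """The forward integration produced a non-finite state.

    Carries ``time_index``, the first microtime index at which the state
    became invalid.
    """

    def __init__(self, message: str, time_index: int):
        super().__init__(message)
        self.time_index = time_index


class InversionFailureError(WcdcmError, RuntimeError):
    """Model inversion could not produce a finite free energy."""


class UndefinedMetricError(WcdcmError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero-variance data)."""


class NumericalConditioningError(WcdcmError, RuntimeError):
    """A covariance or precision matrix is numerically singular."""


class FormatError(WcdcmError, ValueError):
    """A text file violates the expected on-disk format."""
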