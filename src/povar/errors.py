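"""Exception hierarchy for the povar pipeline.

Every stage raises a subclass of :class:`PovarError` so pipeline callers can
attach stage names without catching bare ``ValueError``.
"""


class PovarError(Exception):
    """Base class for all povar errors."""


class InvalidParameterError(PovarError, ValueError):
    """A numeric parameter violates its contract (sign, range, Nyquist...)."""


class UnsupportedParadigmError(PovarError, ValueError):
    """Operation called with a stimulus paradigm it does not handle."""


class InsufficientDataError(PovarError, ValueError):
    """Too little usable data (duration, cycles, slow segments) for the fit."""


class InvalidWindowError(PovarError, ValueError):
    """Analysis window empty or outside the trace."""


class UnreliableEstimateError(PovarError, ValueError):
    """Estimate contract not met (e.g. too few slow-labelled samples)."""


class TrackingFailedError(PovarError, RuntimeError):
    """Pupil tracking failed on every frame."""


class InvalidTrajectoryError(PovarError, ValueError):
    """Synthetic pupil trajectory leaves the frame."""


class FitFailedError(PovarError, RuntimeError):
    """Model fit failed (non-decaying data, sign changes, no convergence)."""


class UndefinedRatioError(PovarError, ZeroDivisionError):
    """Asymmetry ratio requested with a zero denominator."""


class UndefinedGainError(PovarError, ZeroDivisionError):
    """Gain requested with a zero stimulus amplitude."""


class SimulationUnstableError(PovarError, RuntimeError):
    """Internal-model integration produced NaN or diverged."""


class IncompatibleRecordingsError(PovarError, ValueError):
    """Paired analysis given recordings with mismatched stimulus profiles."""
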