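"""Exception and warning types used across larvataxis."""


class LarvataxisError(Exception):
    """Base class for all larvataxis errors."""


class NegativeIntensityError(LarvataxisError, ValueError):
    """A light field takes a negative irradiance somewhere on the plate."""


class DegenerateDesignError(LarvataxisError, ValueError):
    """Too few or collinear points for a planar least-squares fit."""


class RangeError(LarvataxisError, ValueError):
    """Requested integration band lies outside the measured spectrum."""


class DomainError(LarvataxisError, ValueError):
    """A heading angle falls outside [0, 180] degrees."""


class ZeroStepError(LarvataxisError, ValueError):
    """A step angle was requested for a zero-length displacement."""


class EmptyTrajectoryError(LarvataxisError, ValueError):
    """A metric was requested for a trajectory with no accepted steps."""


class BinMismatchError(LarvataxisError, ValueError):
    """Two angular distributions do not share the same binning."""


class ConvergenceError(LarvataxisError, RuntimeError):
    """A least-squares fit failed to converge or was degenerate."""


class UnreachableTargetError(LarvataxisError, ValueError):
    """A calibration target cannot be met by any parameter value.

    Raised e.g. for a target navigation index of 0 (any effective
    temperature gives an unbiased chain the same probability, so T is not
    identifiable) or for targets beyond the greedy (T -> 0) limit.
    """


class FormatError(LarvataxisError, ValueError):
    """A track file contains a malformed row."""


class MissingColumnError(LarvataxisError, ValueError):
    """A track file is missing one of the required columns."""


class UnknownFixtureError(LarvataxisError, ValueError):
    """An unknown synthetic-fixture kind was requested."""


class CapExceededWarning(UserWarning):
    """The proposal cap was reached before any other stopping rule."""


class NonConvergenceWarning(UserWarning):
    """Joint refinement stopped at the sweep cap with residuals above tol."""
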