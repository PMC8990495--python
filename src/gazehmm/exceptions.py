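"""Exception hierarchy.

All errors raised deliberately by this package derive from :class:`GazeHMMError`,
so callers can distinguish bad inputs and degenerate models from genuine bugs.
"""


class GazeHMMError(Exception):
    """Base class for all gazehmm errors."""


class InputError(GazeHMMError, ValueError):
    """An argument violates a documented precondition."""


class ModelDegeneracyError(GazeHMMError):
    """A model parameter is numerically unusable (e.g. singular ROI covariance)."""


class DegenerateVarianceError(GazeHMMError):
    """A statistic is undefined because the relevant variance is zero."""


class UnreachablePowerError(GazeHMMError):
    """Requested statistical power cannot be reached within the search bound."""
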