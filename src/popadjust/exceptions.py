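"""Exception hierarchy.

Validation problems (bad inputs, malformed files) raise :class:`ValidationError`;
numerical problems (failed optimisation, degenerate integrals, loss of overlap)
raise subclasses of :class:`NumericalError`. The CLI maps the former to exit
code 2 and the latter to exit code 3.
"""


class PopAdjustError(Exception):
    """Base class for all errors raised by popadjust."""


class ValidationError(PopAdjustError, ValueError):
    """Invalid inputs: broken invariants, malformed data, bad arguments."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending line/column."""


class NumericalError(PopAdjustError, RuntimeError):
    """Base class for run-time numerical failures."""


class SimulationError(NumericalError):
    """Outcome simulation produced an invalid probability (identity/log links)."""


class IntegrationError(NumericalError):
    """The population integral hit a non-finite integrand value."""


class ConvergenceError(NumericalError):
    """An iterative fit failed to converge; carries diagnostic detail."""


class OverlapError(NumericalError):
    """MAIC moment targets lie outside the convex hull of the IPD moments.

    No weight solution exists: this is the fundamental inability of
    moment-matching weights to extrapolate beyond the observed population.
    """


class SingularFitError(NumericalError):
    """Separation or rank deficiency made a regression fit singular."""


class DegenerateRatioError(NumericalError):
    """Conditional/marginal ratio requested where the marginal effect is zero."""
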