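"""Exception hierarchy for the cost-effectiveness pipeline.

Every stage raises a subclass of :class:`CEAError` so callers can catch
pipeline failures without swallowing programming errors.
"""


class CEAError(Exception):
    """Base class for all package errors."""


class UnsupportedDistributionError(CEAError):
    """A distribution family id is not in the supported candidate set."""


class EmptyInputError(CEAError):
    """An operation received an empty record/draw collection."""


class InvalidCurveError(CEAError):
    """A survival curve violates its invariants (e.g. survival increases)."""


class InfeasibleInputError(CEAError):
    """A risk table is inconsistent with the curve it accompanies."""


class NoEventsError(CEAError):
    """Parametric fitting requires at least one observed event."""


class FitFailureError(CEAError):
    """The likelihood optimizer failed to converge."""


class AbsorbedStateError(CEAError):
    """Transition probability requested from a state with zero survival."""


class InconsistentCurvesError(CEAError):
    """PFS exceeds OS beyond numerical tolerance."""


class ConfigError(CEAError):
    """Analysis configuration failed schema validation."""


class NoCrossingError(CEAError):
    """Threshold search bracket does not contain an ICER = WTP crossing."""


class DistributionSpecError(CEAError):
    """A PSA distribution persistently produces invalid parameter draws."""
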