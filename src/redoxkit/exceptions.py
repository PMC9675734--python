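"""Exception hierarchy for redoxkit."""


class RedoxkitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RedoxkitError, ValueError):
    """A generator or analysis configuration violates its invariants."""


class InsufficientData(RedoxkitError, ValueError):
    """Too few observations for the requested estimate."""


class NoDecayRegion(RedoxkitError):
    """No exponential window above the leakage floor in an I-z curve."""


class FitFailure(RedoxkitError):
    """A nonlinear fit failed to converge."""


class InvalidWindow(RedoxkitError, ValueError):
    """A rolling/estimation window does not fit the data."""


class InvalidBias(RedoxkitError, ValueError):
    """Zero or invalid bias voltage where a conductance is required."""


class EmptyMap(RedoxkitError, ValueError):
    """No events available to build a 2D blink map."""


class BaselineUndefined(RedoxkitError):
    """A force curve has no far-retraction tail to define zero force."""


class DomainError(RedoxkitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InitFailure(RedoxkitError):
    """An initializer could not produce a usable starting estimate."""


class InvalidGrid(RedoxkitError, ValueError):
    """A voxel grid request is incompatible with the data extent."""


class OutOfBounds(RedoxkitError, ValueError):
    """A region of interest falls outside the available grid."""


class PathologicalField(RedoxkitError):
    """Rejection sampling acceptance rate collapsed (field too extreme)."""


class StepTooLarge(RedoxkitError):
    """A Brownian-dynamics step traverses more than ~kT of potential."""
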