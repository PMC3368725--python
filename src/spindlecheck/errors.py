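"""Exception hierarchy for spindlecheck."""


class SpindleCheckError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpindleCheckError, ValueError):
    """A physical or kinetic parameter violates its constraints."""


class ConfigError(SpindleCheckError, ValueError):
    """A configuration file or mapping is malformed or contradictory."""


class NumericalIntegrationError(SpindleCheckError, RuntimeError):
    """A stiff ODE integration failed; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoStationaryDistributionError(SpindleCheckError, ValueError):
    """The requested chain has no proper stationary law (k_-1 = 0, lambda > 0)."""


class DivergentMeanTimeError(SpindleCheckError, ValueError):
    """The mean first-passage time is infinite for the given setup."""


class BracketError(SpindleCheckError, ValueError):
    """A root-bracketing interval does not contain a sign change."""
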