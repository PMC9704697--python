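"""Exception types shared across the package."""


class AnlsLtpError(Exception):
    """Base class for package errors."""


class InvalidStateError(AnlsLtpError):
    """A state vector violates an invariant (negative, non-finite, pool)."""


class NoSteadyStateError(AnlsLtpError):
    """The resting-state solver failed to converge."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class ScheduleError(AnlsLtpError):
    """A stimulation protocol's rates and counts produce overlapping events."""


class EventOrderError(AnlsLtpError):
    """Spike events were supplied out of order."""


class ConditionError(AnlsLtpError):
    """Unknown pharmacology condition or conflicting overrides."""


class CoverageError(AnlsLtpError):
    """A trajectory does not cover the required classification window."""


class FitProtocolError(AnlsLtpError):
    """Invalid calibration setup (e.g. overlapping fit/validation sets)."""


class IntegrationError(AnlsLtpError):
    """The stiff integrator failed; carries the last good state."""

    def __init__(self, message, t=None, y=None):
        super().__init__(message)
        self.t = t
        self.y = y
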