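"""Exception hierarchy shared across the toolkit."""


class DopacycleError(Exception):
    """Base class for all toolkit errors."""


class InvalidSequenceError(DopacycleError, ValueError):
    """A nucleotide sequence violates the Shine-Dalgarno contract.

    Carries the offending position (0-based) when one can be named.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class ValidationError(DopacycleError, ValueError):
    """An input value violates a documented precondition."""


class IntegrationError(DopacycleError, RuntimeError):
    """The ODE solver failed to meet its tolerance.

    ``last_state`` holds the last accepted state vector, if any.
    """

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class InsufficientDataError(DopacycleError, ValueError):
    """Too few observations to run the requested analysis."""
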