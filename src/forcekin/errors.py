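"""Exception hierarchy shared across the package."""


class ForcekinError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ForcekinError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(ForcekinError):
    """Not enough data points/segments/groups to perform the operation."""


class NumericsError(ForcekinError):
    """A numerical routine (root finding, curve fit) failed to converge.

    ``diagnostics`` carries whatever the routine knows about the failure
    (brackets tried, initializations, residuals).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SimulationError(ForcekinError):
    """The simulator was asked for a physically inconsistent configuration."""
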