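"""Exception hierarchy for driftshift."""


class DriftshiftError(Exception):
    """Base class for all package errors."""


class TreeFormatError(DriftshiftError):
    """A tree file could not be parsed under the requested dialect."""


class ValidationError(DriftshiftError):
    """Input violated a structural contract (tip sets, labels, finiteness)."""


class UltrametricityError(ValidationError):
    """Root-to-tip depths deviate beyond tolerance; reports the worst tip."""

    def __init__(self, message, worst_tip=None, deviation=None):
        super().__init__(message)
        self.worst_tip = worst_tip
        self.deviation = deviation


class GridCoverageError(DriftshiftError):
    """Probability mass reached the character-grid boundary (grid too narrow)."""


class UnidentifiableError(DriftshiftError):
    """Likelihood surface is flat; the parameter is not identifiable."""


class FitError(DriftshiftError):
    """Optimizer failed to converge from every starting point."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SimulationExtinctError(DriftshiftError):
    """Forward birth-death simulation went extinct before the stop condition."""

    def __init__(self, message, attempts=1):
        super().__init__(message)
        self.attempts = attempts
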