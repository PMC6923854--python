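"""Package-wide exception types."""


class ClonalPairError(Exception):
    """Base class for package errors."""


class ParameterError(ClonalPairError, ValueError):
    """Invalid or infeasible parameter set."""


class SimulationError(ClonalPairError, RuntimeError):
    """Simulation could not satisfy its constraints (e.g. event placement)."""


class AnnotationError(ClonalPairError, ValueError):
    """Inconsistent genome annotation (e.g. CDS length not a multiple of 3)."""


class InputError(ClonalPairError, ValueError):
    """Invalid user input to an analysis operation."""


class UndefinedResultError(ClonalPairError, ArithmeticError):
    """The requested statistic is undefined for this input (e.g. 0/0)."""
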