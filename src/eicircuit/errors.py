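"""Exception types shared across the package."""


class EICircuitError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(EICircuitError):
    """Invalid patch geometry (e.g. patch too small, non-square pixel count)."""


class FormatError(EICircuitError):
    """Malformed archive or configuration contents."""


class ParameterError(EICircuitError):
    """A numeric parameter is outside its admissible range."""


class AliasingError(ParameterError):
    """A grating frequency exceeds the Nyquist limit of the pixel grid."""


class IntegrationDivergedError(EICircuitError):
    """A forward-Euler simulation produced a non-finite state."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


class SolverDivergedError(EICircuitError):
    """The ADMM residual grew for too many consecutive iterations."""


class AssemblyError(EICircuitError):
    """A Dale's-law sign violation was found while assembling a network."""


class UndefinedStatisticError(EICircuitError):
    """A requested ratio or fraction has a zero denominator."""
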