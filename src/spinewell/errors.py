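"""Exception types shared across the package."""


class SpinewellError(Exception):
    """Base class for all package-specific errors."""


class InvalidKinematicsError(SpinewellError):
    """Deformation state is not physically admissible (J <= 0, non-unit fiber, ...)."""


class InvalidStrainError(SpinewellError):
    """Contractile-element strain outside the admissible range (element annihilated)."""


class ConfigError(SpinewellError):
    """A configuration file or table is incomplete or inconsistent."""


class ConvergenceError(SpinewellError):
    """An implicit solve failed to converge; carries diagnostic information."""

    def __init__(self, message, step=None, residual=None, history=None):
        super().__init__(message)
        self.step = step
        self.residual = residual
        self.history = history or []
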