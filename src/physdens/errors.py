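"""Exception hierarchy shared across the package."""


class PhysdensError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PhysdensError, ValueError):
    """An argument violates the mathematical domain of an operation."""


class DegenerateInputError(PhysdensError, ValueError):
    """Inputs are formally admissible but make the problem degenerate."""


class ConfigError(PhysdensError, ValueError):
    """A configuration object is internally inconsistent."""


class SolverError(PhysdensError, RuntimeError):
    """A numeric solver failed; carries diagnostics where available."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitError(SolverError):
    """Maximum-likelihood estimation did not converge; carries best state."""
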