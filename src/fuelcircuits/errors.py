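"""Exception hierarchy shared across the package."""


class FuelCircuitsError(Exception):
    """Base class for package errors."""


class ConfigurationError(FuelCircuitsError, ValueError):
    """Invalid model options, missing rate constants, or bad run configuration."""


class ValidationError(FuelCircuitsError, ValueError):
    """Input data violate a documented precondition (degenerate or inconsistent)."""


class IntegrationError(FuelCircuitsError, RuntimeError):
    """ODE solver failure; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
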