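"""Exception hierarchy.

Validation errors (bad inputs, bad config) are distinguished from numerical
failures (integration, fit non-convergence, degenerate data) so the CLI can
map them to distinct exit codes.
"""


class DRLError(Exception):
    """Base class for all drlkit errors."""


class ValidationError(DRLError, ValueError):
    """Invalid user input: parameters, configuration, or data contracts."""


class IntegrationError(DRLError, RuntimeError):
    """ODE integration did not meet its tolerances; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitError(DRLError, RuntimeError):
    """Base class for fitting failures."""


class FitConvergenceError(FitError):
    """The least-squares optimizer failed to converge."""


class DegenerateDataError(FitError):
    """Data carry no rate information (flat traces: rate unidentifiable)."""
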