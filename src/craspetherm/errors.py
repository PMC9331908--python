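"""Exception hierarchy shared across the package."""


class CraspethermError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CraspethermError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(CraspethermError, ValueError):
    """Too few observations to fit the requested model."""


class NonConvergenceError(CraspethermError, RuntimeError):
    """No optimizer start converged.

    Carries per-start diagnostics in ``diagnostics`` (list of dicts with
    keys ``start``, ``status``, ``message``).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class BootstrapFailureError(CraspethermError, RuntimeError):
    """More than half of the bootstrap replicate refits failed."""


class RasterFormatError(CraspethermError, ValueError):
    """A raster file or stack violates the expected format."""


class ConfigError(CraspethermError, ValueError):
    """Pipeline configuration failed validation."""
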