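"""Exception types shared across the package."""


class VirtpolError(Exception):
    """Base class for package errors."""


class ValidationError(VirtpolError, ValueError):
    """A parameter or input violates a documented precondition."""


class ShapeError(VirtpolError, ValueError):
    """An array has an incompatible or unsupported shape."""


class RegistrationFailureError(VirtpolError, RuntimeError):
    """Registration could not be estimated (too few matches / no structure)."""


class CheckpointError(VirtpolError, RuntimeError):
    """A checkpoint is missing, corrupt, or version-incompatible."""
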