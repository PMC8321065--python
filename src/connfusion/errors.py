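"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError and subclasses -> 2,
everything else raised by pipeline stages -> 3.
"""


class ConnfusionError(Exception):
    """Base class for all package errors."""


class ValidationError(ConnfusionError):
    """Input violates a documented contract (bad labels, bad dims, ...)."""


class DimensionalityError(ValidationError):
    """An image does not have the required number of axes."""


class GeometryError(ValidationError):
    """Two volumes that must share a voxel grid do not."""


class ShapeError(ValidationError):
    """An array's shape is incompatible with a network layer."""


class DivergenceError(ConnfusionError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class CheckpointError(ConnfusionError):
    """A saved model state is missing or incompatible."""
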