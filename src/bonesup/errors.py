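"""Exception hierarchy shared across the pipeline stages."""


class BonesupError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BonesupError):
    """A configuration value or range is invalid or infeasible."""


class GeometryError(BonesupError):
    """Phantom geometry cannot be rasterized on the requested grid."""


class SizeError(BonesupError):
    """An image is too small for the requested operation."""


class DegenerateWindowError(BonesupError):
    """Normalization window has zero width."""


class NumericalError(BonesupError):
    """A numerical failure (non-finite activations/losses) occurred."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class IdenticalImagesError(BonesupError):
    """PSNR requested for identical images: MSE is zero, PSNR is unbounded.

    Reported as a distinct condition instead of +inf so report files can
    store it as null with a flag.
    """


class DependencyError(BonesupError):
    """A pipeline stage was requested before its upstream stage produced output."""
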