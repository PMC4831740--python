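"""Exception hierarchy shared across the pipeline stages."""


class CTStainError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CTStainError, ValueError):
    """A configuration value or function argument violates its contract."""


class DegeneratePhantomError(ValidationError):
    """Phantom parameters produce a sample too small to rasterise (< 3 px radius)."""


class DetectionError(CTStainError):
    """An image-analysis detector could not produce a result."""


class NoEdgeError(DetectionError):
    """No sample edge could be located on a line profile (e.g. flat profile)."""


class FitError(CTStainError):
    """A model fit failed to converge or was unidentifiable."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SegmentationError(CTStainError):
    """Thresholding produced an empty foreground."""
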