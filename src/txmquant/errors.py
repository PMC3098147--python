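"""Exception hierarchy for txmquant."""


class TxmQuantError(Exception):
    """Base class for all txmquant errors."""


class ConfigError(TxmQuantError, ValueError):
    """Invalid configuration or invalid input parameters."""


class PlacementError(TxmQuantError, RuntimeError):
    """Cluster placement failed after the configured number of attempts."""


class GeometryError(TxmQuantError, ValueError):
    """Unsupported imaging geometry (e.g. anisotropic voxel pitch)."""


class NormalizationError(TxmQuantError, ValueError):
    """Flat-field normalization failed (non-positive flat-field pixels)."""


class DegenerateImageError(TxmQuantError, ValueError):
    """Image histogram is degenerate (e.g. constant image for Otsu)."""


class InsufficientAnglesError(TxmQuantError, ValueError):
    """Tomographic reconstruction requires at least two distinct angles."""


class StageError(TxmQuantError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class PatchworkGapWarning(UserWarning):
    """Mosaic tiles leave uncovered interior pixels."""


class EmptyMaskWarning(UserWarning):
    """A supplied mask is empty; dependent quantities are flagged."""
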