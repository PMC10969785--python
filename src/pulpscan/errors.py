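"""Exception types raised by the segmentation pipeline and phantom generator."""


class PulpscanError(Exception):
    """Base class for all package errors."""


class GeometryError(PulpscanError, ValueError):
    """Phantom geometry is inconsistent (e.g. cavity larger than the fruit interior)."""


class SegmentationError(PulpscanError, RuntimeError):
    """A segmentation stage could not produce a usable result."""


class NoCavityError(SegmentationError):
    """No dark candidate component was found inside the fruit mask."""


class EmptyMaskError(SegmentationError):
    """Erosion (or refinement) removed every foreground pixel."""


class SeedPointError(SegmentationError):
    """The region-growing seed does not lie inside an enclosed cavity region."""


class StageError(SegmentationError):
    """Wraps a stage failure with the name of the failing pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage} failed: {original}")
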