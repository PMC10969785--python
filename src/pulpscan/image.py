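"""Lightweight containers for grayscale and binary section images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale section image.

    Parameters
    ----------
    pixels:
        2-D array of intensities (any float or integer dtype).
    value_range:
        Inclusive (min, max) of valid intensities, normally set from the
        source bit depth (e.g. (0, 255) for 8-bit, (0, 65535) for 16-bit).
    section_kind:
        ``"cross"`` for an equatorial section, ``"longitudinal"`` for an
        axial one.  The default fruit-mask erosion radius depends on it.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)
    section_kind: str = "cross"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale image, got ndim={px.ndim}")
        lo, hi = self.value_range
        if lo >= hi:
            raise ValueError(f"invalid value_range {self.value_range}")
        if px.size and (px.min() < lo or px.max() > hi):
            raise ValueError(
                f"pixel values [{px.min()}, {px.max()}] fall outside "
                f"value_range {self.value_range}"
            )
        if self.section_kind not in ("cross", "longitudinal"):
            raise ValueError(f"unknown section_kind {self.section_kind!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryImage:
    """A boolean foreground/background image produced by a pipeline stage."""

    pixels: np.ndarray
    provenance: str = ""
    threshold: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D binary image, got ndim={px.ndim}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        """Foreground pixel count."""
        return int(self.pixels.sum())
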