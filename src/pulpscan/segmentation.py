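"""Mask-based extraction of the central pulp cavity from a section image.

The pipeline runs seven stages on a grayscale section:

A. binarize           -- global threshold; bright tissue becomes foreground
B. build_mask         -- largest component, hole-filled, eroded by a disk
                         ("erosion core") so peel and exterior are excluded
C. apply_mask         -- pixelwise multiplication of image and mask
D. isolate_cavity     -- dark pixels inside the mask; keep the component
                         whose centroid is nearest the fruit centroid
E/F. refine           -- dilation then erosion, separating enclosed bright
                         blockage from any connection to the exterior
G. fill_by_region_growing -- grow from a seed across everything enclosed by
                         the cavity boundary, dark and bright alike

For an unblocked cavity the area is the dark component's pixel count; for a
blocked one it is the filled count, so displaced pulp inside the cavity is
absorbed into the measurement.

All thresholds use a strict ``>`` for foreground, pixels beyond the frame
count as background, and components/growth are 8-connected by default;
these conventions keep re-runs bit-stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import (
    EmptyMaskError,
    NoCavityError,
    SeedPointError,
    StageError,
)
from .image import BinaryImage, GrayImage

# ---------------------------------------------------------------------------
# morphology primitives
#
# Set definitions (used verbatim by the brute-force test oracles):
#   erosion:  p stays foreground iff every structuring-element offset from p
#             lands on a foreground pixel; offsets falling outside the frame
#             count as background.
#   dilation: p becomes foreground iff some offset from p lands on a
#             foreground pixel.


def disk_selem(radius: float) -> np.ndarray:
    """Disk structuring element: offsets with Euclidean norm <= radius."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(math.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return np.hypot(yy, xx) <= radius


def connectivity_selem(connectivity: int) -> np.ndarray:
    """3x3 structuring element for 4- or 8-connectivity."""
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def erode(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    return ndimage.binary_erosion(mask, structure=selem, border_value=0)


def dilate(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=selem, border_value=0)


def region_grow(allowed: np.ndarray, seed: tuple[int, int], connectivity: int = 8) -> np.ndarray:
    """Connected region of ``allowed`` pixels containing ``seed``.

    Raises :class:`SeedPointError` if the seed pixel is not allowed.
    """
    allowed = np.asarray(allowed, dtype=bool)
    r, c = seed
    if not (0 <= r < allowed.shape[0] and 0 <= c < allowed.shape[1]):
        raise SeedPointError(f"seed {seed} lies outside the image")
    if not allowed[r, c]:
        raise SeedPointError(f"seed {seed} is not inside a growable region")
    labeled, _ = ndimage.label(allowed, structure=connectivity_selem(connectivity))
    return labeled == labeled[r, c]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the cavity-extraction pipeline.

    The erosion core must be large enough that the mask retreats from the
    peel on every section; the right size differs between cross and
    longitudinal sections, so a per-kind default is kept (15 / 25 px at
    512x512, calibrated on the phantom suite) unless ``erosion_core_radius``
    overrides it.
    """

    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    erosion_core_radius: float | None = None
    erosion_core_radius_cross: float = 15.0
    erosion_core_radius_longitudinal: float = 25.0
    refine_dilate_radius: float = 3.0
    refine_erode_radius: float = 3.0
    connectivity: int = 8
    blockage_area_fraction_threshold: float = 0.01
    seed_rule: str = "cavity_centroid"  # "cavity_centroid" | "image_center" | "explicit"
    seed_point: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        for r in (
            self.erosion_core_radius_cross,
            self.erosion_core_radius_longitudinal,
            self.refine_dilate_radius,
            self.refine_erode_radius,
        ):
            if r < 0:
                raise ValueError("radii must be non-negative")
        if self.erosion_core_radius is not None and self.erosion_core_radius < 0:
            raise ValueError("radii must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not (0.0 < self.blockage_area_fraction_threshold < 1.0):
            raise ValueError("blockage threshold must lie in (0, 1)")
        if self.seed_rule not in ("cavity_centroid", "image_center", "explicit"):
            raise ValueError(f"unknown seed_rule {self.seed_rule!r}")
        if self.seed_rule == "explicit" and self.seed_point is None:
            raise ValueError("explicit seed_rule requires seed_point")

    def core_radius_for(self, section_kind: str) -> float:
        if self.erosion_core_radius is not None:
            return self.erosion_core_radius
        if section_kind == "longitudinal":
            return self.erosion_core_radius_longitudinal
        return self.erosion_core_radius_cross


@dataclass(frozen=True)
class CavityResult:
    """Final cavity mask, its pixel area, and all stage intermediates."""

    filled_mask: BinaryImage
    area_px: int
    blocked: bool
    threshold: float
    intermediates: dict = field(compare=False)


# ---------------------------------------------------------------------------
# stages


def _threshold_of(values: np.ndarray, config: SegmentationConfig | None) -> float:
    if config is not None and config.threshold_method == "fixed":
        return float(config.fixed_threshold)
    return float(threshold_otsu(values))


def binarize(image: GrayImage, method: str = "otsu", value: float | None = None) -> BinaryImage:
    """Stage A: threshold the section; foreground is strictly above threshold.

    With ``method="otsu"`` a constant image cannot be thresholded; a warning
    is emitted and an all-background image returned.
    """
    px = image.pixels
    if method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a threshold value")
        thr = float(value)
    elif method == "otsu":
        if px.size == 0:
            raise ValueError("empty image")
        if np.ptp(px) == 0:
            warnings.warn(
                "constant image: Otsu threshold undefined, returning all background",
                RuntimeWarning,
                stacklevel=2,
            )
            return BinaryImage(np.zeros(px.shape, dtype=bool), "binarized", None)
        thr = float(threshold_otsu(px))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryImage(px > thr, "binarized", thr)


def build_mask(
    binary: BinaryImage,
    erosion_core_radius: float,
    *,
    selem: np.ndarray | None = None,
) -> BinaryImage:
    """Stage B: hole-filled largest foreground component, eroded by a disk.

    The largest component is the fruit disk; filling its holes keeps the
    cavity inside the mask, and the erosion retreats the mask boundary past
    the peel.  ``selem`` overrides the disk element (mainly for tests).
    """
    if erosion_core_radius < 0:
        raise ValueError("erosion core radius must be non-negative")
    fg = binary.pixels
    labeled, n = ndimage.label(fg, structure=connectivity_selem(8))
    if n == 0:
        raise EmptyMaskError("no foreground component to build a mask from")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    largest = labeled == (int(np.argmax(sizes)) + 1)
    filled = ndimage.binary_fill_holes(largest)
    if selem is None:
        selem = disk_selem(erosion_core_radius)
    eroded = erode(filled, selem)
    if not eroded.any():
        raise EmptyMaskError(
            f"erosion core (radius {erosion_core_radius}) annihilated the fruit mask"
        )
    return BinaryImage(eroded, "mask")


def apply_mask(image: GrayImage, mask: BinaryImage) -> GrayImage:
    """Stage C: keep intensities inside the mask, zero elsewhere."""
    if image.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"image {image.pixels.shape} and mask {mask.pixels.shape} dimensions differ"
        )
    out = np.where(mask.pixels, image.pixels, 0)
    lo, hi = image.value_range
    lo = min(lo, 0.0)
    return GrayImage(out, (lo, hi), image.section_kind)


def _mask_region(masked: GrayImage) -> np.ndarray:
    """Recover the in-mask region of a masked image.

    The exterior is the zero-valued area connected to the frame border;
    everything else (including dark cavity pixels) is inside the mask.
    """
    zeros = masked.pixels <= 0
    if not zeros.any():
        return np.ones(masked.pixels.shape, dtype=bool)
    labeled, n = ndimage.label(zeros, structure=connectivity_selem(8))
    border_labels = np.unique(
        np.concatenate([labeled[0], labeled[-1], labeled[:, 0], labeled[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    exterior = np.isin(labeled, border_labels)
    return ~exterior


def isolate_cavity(
    masked: GrayImage, config: SegmentationConfig | None = None
) -> BinaryImage:
    """Stage D: the dark candidate component nearest the fruit centroid.

    Dark (at-or-below-threshold) pixels inside the mask become candidates;
    the zeroed exterior is kept as background so it cannot merge with the
    cavity.  Among candidate components the cavity is the one whose centroid
    is nearest the fruit centroid, ties broken toward the larger area.
    """
    config = config or SegmentationConfig()
    region = _mask_region(masked)
    inside = masked.pixels[region]
    if inside.size == 0 or (config.threshold_method == "otsu" and np.ptp(inside) == 0):
        raise NoCavityError("no cavity found: mask interior has no dark component")
    thr = _threshold_of(inside, config)
    candidates = region & ~(masked.pixels > thr)
    labeled, n = ndimage.label(candidates, structure=connectivity_selem(config.connectivity))
    if n == 0:
        raise NoCavityError("no cavity found: no dark component inside the mask")
    fruit_centroid = np.array(ndimage.center_of_mass(region))
    coms = np.array(ndimage.center_of_mass(candidates, labeled, range(1, n + 1)))
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    dists = np.hypot(*(coms - fruit_centroid).T)
    # round distances so exact geometric ties resolve by area
    order = sorted(range(n), key=lambda i: (round(dists[i], 6), -sizes[i]))
    chosen = order[0] + 1
    return BinaryImage(labeled == chosen, "cavity_candidate", thr)


def refine(candidate: BinaryImage, config: SegmentationConfig | None = None) -> BinaryImage:
    """Stages E/F: dilation then erosion of the candidate cavity.

    Closes thin leaks between the cavity interior and the exterior so that
    enclosed bright blockage stays enclosed.  Radii (0, 0) are the identity.
    """
    config = config or SegmentationConfig()
    if not candidate.pixels.any():
        raise EmptyMaskError("refine called on an empty candidate")
    out = candidate.pixels
    if config.refine_dilate_radius > 0:
        out = dilate(out, disk_selem(config.refine_dilate_radius))
    if config.refine_erode_radius > 0:
        out = erode(out, disk_selem(config.refine_erode_radius))
    if not out.any():
        raise EmptyMaskError("refinement erosion emptied the cavity mask")
    return BinaryImage(out, "refined", candidate.threshold)


def _seed_for(mask: np.ndarray, allowed: np.ndarray, config: SegmentationConfig) -> tuple[int, int]:
    if config.seed_rule == "explicit":
        return tuple(config.seed_point)
    if config.seed_rule == "image_center":
        return (mask.shape[0] // 2, mask.shape[1] // 2)
    # cavity_centroid: centroid of the candidate, snapped to the nearest
    # growable pixel when the centroid itself falls in a hole of a very
    # non-convex cavity
    com = ndimage.center_of_mass(mask)
    r, c = int(round(com[0])), int(round(com[1]))
    r = min(max(r, 0), mask.shape[0] - 1)
    c = min(max(c, 0), mask.shape[1] - 1)
    if allowed[r, c]:
        return (r, c)
    pts = np.argwhere(allowed & (mask | ndimage.binary_dilation(mask)))
    if not len(pts):
        raise SeedPointError("no growable pixel near the cavity centroid")
    d = np.hypot(pts[:, 0] - com[0], pts[:, 1] - com[1])
    return tuple(pts[int(np.argmin(d))])


def fill_by_region_growing(
    candidate: BinaryImage, config: SegmentationConfig | None = None
) -> BinaryImage:
    """Stage G: grow from a seed across everything the cavity encloses.

    Background connected to the frame border is ungrowable; the seed region
    therefore expands over the dark cavity pixels and any bright blockage
    holes they enclose, yielding the fully filled cavity.
    """
    config = config or SegmentationConfig()
    fg = candidate.pixels
    bg_conn = 4 if config.connectivity == 8 else 8
    labeled, n = ndimage.label(~fg, structure=connectivity_selem(bg_conn))
    border_labels = np.unique(
        np.concatenate([labeled[0], labeled[-1], labeled[:, 0], labeled[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    exterior = np.isin(labeled, border_labels)
    allowed = ~exterior
    seed = _seed_for(fg, allowed, config)
    filled = region_grow(allowed, seed, config.connectivity)
    return BinaryImage(filled, "filled", candidate.threshold)


def classify_blockage(
    candidate: BinaryImage,
    masked: GrayImage,
    config: SegmentationConfig | None = None,
) -> bool:
    """True iff enclosed bright area exceeds the configured cavity fraction.

    Bright pixels fully enclosed by the dark cavity component are its holes;
    the cavity counts as blocked when their area is strictly greater than
    ``blockage_area_fraction_threshold`` times the full cavity area.
    """
    config = config or SegmentationConfig()
    # holes are background components under the connectivity complementary
    # to the foreground connectivity (8-connected cavity -> 4-connected holes)
    filled = ndimage.binary_fill_holes(
        candidate.pixels,
        structure=connectivity_selem(4 if config.connectivity == 8 else 8),
    )
    holes = filled & ~candidate.pixels
    cavity_area = int(filled.sum())
    if cavity_area == 0:
        return False
    return int(holes.sum()) > config.blockage_area_fraction_threshold * cavity_area


def extract_cavity_area(
    image: GrayImage, config: SegmentationConfig | None = None
) -> CavityResult:
    """Run the full A-G pipeline and measure the cavity pixel area.

    Unblocked cavities are measured directly from the refined dark
    component; blocked ones from the region-growing fill, which absorbs the
    bright blockage.  Stage failures are re-raised as :class:`StageError`
    naming the stage.  All intermediates are retained for audit.
    """
    config = config or SegmentationConfig()
    intermediates: dict = {}

    def stage(name, fn):
        try:
            out = fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, exc) from exc
        intermediates[name] = out
        return out

    binary = stage("A_binarize", lambda: binarize(image, config.threshold_method,
                                                  config.fixed_threshold))
    if not binary.pixels.any():
        raise NoCavityError("no cavity found: image contains no foreground tissue")
    mask = stage("B_mask", lambda: build_mask(binary, config.core_radius_for(image.section_kind)))
    masked = stage("C_masked", lambda: apply_mask(image, mask))
    candidate = stage("D_candidate", lambda: isolate_cavity(masked, config))
    refined = stage("EF_refined", lambda: refine(candidate, config))
    blocked = classify_blockage(refined, masked, config)
    filled = stage("G_filled", lambda: fill_by_region_growing(refined, config))

    final = filled if blocked else refined
    return CavityResult(
        filled_mask=BinaryImage(final.pixels, "cavity", refined.threshold),
        area_px=int(final.pixels.sum()),
        blocked=bool(blocked),
        threshold=float(refined.threshold) if refined.threshold is not None else float("nan"),
        intermediates=intermediates,
    )
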