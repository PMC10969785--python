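"""Synthetic mandarin section phantoms with known cavity geometry.

A phantom section mimics the structures visible in a reconstructed CT slice
of a mandarin: a bright peel annulus, mid-intensity pulp divided into wedges
by septa, a dark central cavity (optionally lobed/elliptical), optional
bright pulp fragments lodged inside the cavity ("blockage"), point-like dark
ruptures in the pulp, and additive Gaussian noise.  Every phantom carries an
exact ground-truth label grid, so segmentation accuracy can be scored in
pixels.

Conventions: pixel (r, c) refers to row r, column c (0-based); geometric
tests use the pixel-centre coordinates, with the image centre at
``((n-1)/2, (n-1)/2)``.  The cavity is the darkest interior structure
(the usual CT rendering); set ``IntensityLevels(inverted=True)`` for
bright-cavity modalities.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .image import GrayImage
from . import reference

# label values in the ground-truth grid
BACKGROUND, CAVITY, PULP, SEPTUM, PEEL, BLOCKAGE, RUPTURE = range(7)

#: labels that make up the "cavity region" whose pixel area the pipeline measures
CAVITY_REGION_LABELS = (CAVITY, BLOCKAGE)


@dataclass(frozen=True)
class IntensityLevels:
    """Gray levels assigned to each structure (0-255 scale).

    The cavity must be the darkest interior level; the septum level sits
    close enough to the pulp that a global threshold groups them as tissue.
    """

    background: float = 0.0
    cavity: float = 10.0
    rupture: float = 12.0
    septum: float = 140.0
    pulp: float = 160.0
    blockage: float = 175.0
    peel: float = 230.0
    inverted: bool = False

    def validate(self) -> None:
        interior = {
            "cavity": self.cavity,
            "rupture": self.rupture,
            "septum": self.septum,
            "pulp": self.pulp,
            "blockage": self.blockage,
            "peel": self.peel,
        }
        if len({*interior.values(), self.background}) != 7:
            raise GeometryError("intensity levels must be pairwise distinct")
        darkest = min(interior, key=interior.get)
        if darkest != "cavity":
            raise GeometryError(
                f"cavity must be the darkest interior level, got {darkest}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of one synthetic section.

    ``cavity_radius`` may be a scalar (circular cavity) or an ``(a, b)``
    pair of semi-axes in pixels (row 'b', column 'a' directions).  The lobed
    perturbation multiplies the cavity boundary radius by
    ``1 + lobe_amplitude*cos(lobe_count*theta + phase)`` with a seeded random
    phase, so real-world cavity irregularity is represented without breaking
    the exact ground truth.
    """

    image_size: int = 512
    fruit_radius: float = 220.0
    peel_thickness: float = 18.0
    cavity_radius: float | tuple[float, float] = (40.0, 32.0)
    n_segments: int = 9
    septum_width: float = 3.0
    lobe_amplitude: float = 0.08
    lobe_count: int = 5
    blockage_fraction: float = 0.0
    rupture_count: int = 0
    noise_sd: float = 0.0
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    section_kind: str = "cross"
    seed: int = 0

    def __post_init__(self) -> None:
        cr = self.cavity_radius
        if np.isscalar(cr):
            cr = (float(cr), float(cr))
        else:
            cr = (float(cr[0]), float(cr[1]))
        object.__setattr__(self, "cavity_radius", cr)
        self.validate()

    # fruit semi-axes (row, col); a longitudinal section is taller than wide
    @property
    def fruit_semi_axes(self) -> tuple[float, float]:
        if self.section_kind == "longitudinal":
            return (self.fruit_radius, 0.78 * self.fruit_radius)
        return (self.fruit_radius, self.fruit_radius)

    @property
    def center(self) -> tuple[float, float]:
        c = (self.image_size - 1) / 2.0
        return (c, c)

    def validate(self) -> None:
        if self.image_size < 8:
            raise GeometryError("image_size must be at least 8 pixels")
        if self.section_kind not in ("cross", "longitudinal"):
            raise GeometryError(f"unknown section_kind {self.section_kind!r}")
        if not (0.0 <= self.blockage_fraction <= 1.0):
            raise GeometryError("blockage_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise GeometryError("noise_sd must be non-negative")
        if self.peel_thickness < 0 or self.fruit_radius <= 0:
            raise GeometryError("fruit_radius must be positive, peel_thickness >= 0")
        a, b = self.cavity_radius
        if a < 0 or b < 0:
            raise GeometryError("cavity semi-axes must be non-negative")
        inner = min(self.fruit_semi_axes) - self.peel_thickness
        if max(a, b) * (1 + self.lobe_amplitude) >= inner:
            raise GeometryError(
                f"cavity (max semi-axis {max(a, b)} px, lobes included) does not "
                f"fit inside the fruit interior (radius {inner} px)"
            )
        self.intensity_levels.validate()


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth of a generated section (pre-noise label grid)."""

    cavity_area_px: int
    blockage_area_px: int
    blocked: bool
    spec: PhantomSpec
    labels: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.blockage_area_px > self.cavity_area_px:
            raise ValueError("blockage cannot exceed the cavity area")
        if self.blocked != (self.blockage_area_px > 0):
            raise ValueError("blocked flag inconsistent with blockage area")


@dataclass(frozen=True)
class PhantomPair:
    """A pre/post compression phantom pair with its exact damage rate."""

    pre_image: GrayImage
    pre_truth: PhantomTruth
    post_image: GrayImage
    post_truth: PhantomTruth
    deformation_mm: float
    true_damage_rate: float


@dataclass(frozen=True)
class DamageModel:
    """Maps compression deformation (mm) to cavity growth and blockage.

    The default anchors interpolate the group mean damage rates measured in
    the compression study (3.82, 5.74, 10.81, 16.58 % at 4, 8, 12, 16 mm),
    so phantom groups generated at those deformations reproduce the study's
    damage-rate means.  Blockage appears from 12 mm, where displaced pulp
    was first observed inside the cavity, and grows with deformation.  Both
    maps are monotone non-decreasing, with linear extrapolation beyond the
    last anchor.
    """

    deformation_anchors_mm: tuple[float, ...] = (0.0,) + reference.DEFORMATIONS_MM
    damage_pct_anchors: tuple[float, ...] = (0.0,) + reference.DAMAGE_RATE_MEAN_PCT
    blockage_anchors_mm: tuple[float, ...] = (0.0, 8.0, 12.0, 16.0)
    blockage_fraction_anchors: tuple[float, ...] = (0.0, 0.0, 0.12, 0.20)
    blockage_fraction_cap: float = 0.30

    def area_scale(self, deformation_mm: float) -> float:
        """Factor by which the cavity area grows at this deformation."""
        if deformation_mm < 0:
            raise ValueError("deformation must be non-negative")
        pct = _interp_extrap(
            deformation_mm, self.deformation_anchors_mm, self.damage_pct_anchors
        )
        return 1.0 + pct / 100.0

    def blockage_fraction(self, deformation_mm: float) -> float:
        if deformation_mm < 0:
            raise ValueError("deformation must be non-negative")
        f = _interp_extrap(
            deformation_mm, self.blockage_anchors_mm, self.blockage_fraction_anchors
        )
        return float(min(max(f, 0.0), self.blockage_fraction_cap))


class IdentityDamageModel(DamageModel):
    """No cavity growth, no blockage, at any deformation (null model)."""

    def area_scale(self, deformation_mm: float) -> float:  # noqa: D102
        if deformation_mm < 0:
            raise ValueError("deformation must be non-negative")
        return 1.0

    def blockage_fraction(self, deformation_mm: float) -> float:  # noqa: D102
        if deformation_mm < 0:
            raise ValueError("deformation must be non-negative")
        return 0.0


def _interp_extrap(x: float, xs: tuple[float, ...], ys: tuple[float, ...]) -> float:
    """Piecewise-linear interpolation with linear extrapolation past the ends."""
    if x >= xs[-1] and len(xs) >= 2:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return ys[-1] + slope * (x - xs[-1])
    return float(np.interp(x, xs, ys))


# ---------------------------------------------------------------------------
# generation

def generate_section(spec: PhantomSpec) -> tuple[GrayImage, PhantomTruth]:
    """Render one section phantom and its exact ground truth.

    The label grid is built structure by structure (interior pulp, septa,
    cavity, blockage fragments, ruptures, peel); ``truth.cavity_area_px`` is
    the exact count of pixels labelled cavity or blockage before noise.
    Identical ``spec`` (including its seed) gives byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    cy, cx = spec.center
    rr, cc = np.mgrid[0:n, 0:n]
    dy = rr - cy
    dx = cc - cx

    fb, fa = spec.fruit_semi_axes  # (row, col) semi-axes
    fruit = (dy / fb) ** 2 + (dx / fa) ** 2 <= 1.0
    ib, ia = fb - spec.peel_thickness, fa - spec.peel_thickness
    interior = (dy / ib) ** 2 + (dx / ia) ** 2 <= 1.0 if min(ia, ib) > 0 else np.zeros_like(fruit)

    # lobed elliptical cavity; the random phase is always drawn so the
    # rng stream is identical whether or not lobes are enabled
    phase = rng.uniform(0.0, 2.0 * math.pi)
    a, b = spec.cavity_radius
    if a > 0 and b > 0:
        rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
        theta = np.arctan2(dy, dx)
        boundary = 1.0 + spec.lobe_amplitude * np.cos(spec.lobe_count * theta + phase)
        cavity = rho <= boundary
    else:
        cavity = np.zeros_like(fruit)

    # septa: thin radial walls between pulp wedges, constant pixel width
    septum_offset = rng.uniform(0.0, 2.0 * math.pi)
    septa = np.zeros_like(fruit)
    if spec.n_segments > 0 and spec.septum_width > 0:
        theta_all = np.arctan2(dy, dx)
        wedge = 2.0 * math.pi / spec.n_segments
        ang = np.mod(theta_all - septum_offset, wedge)
        ang = np.minimum(ang, wedge - ang)  # angular distance to nearest wall
        r = np.hypot(dy, dx)
        septa = interior & ~cavity & (ang * r <= spec.septum_width / 2.0)

    labels = np.full((n, n), BACKGROUND, dtype=np.uint8)
    labels[fruit] = PEEL
    labels[interior] = PULP
    labels[septa] = SEPTUM
    labels[cavity & interior] = CAVITY
    cavity_mask = labels == CAVITY

    blockage = _place_blockage(cavity_mask, spec.blockage_fraction, rng)
    labels[blockage] = BLOCKAGE

    ruptures = _place_ruptures(labels, cavity_mask, spec.rupture_count, rng)
    labels[ruptures] = RUPTURE

    lv = spec.intensity_levels
    lut = np.array(
        [lv.background, lv.cavity, lv.pulp, lv.septum, lv.peel, lv.blockage, lv.rupture],
        dtype=np.float32,
    )
    pixels = lut[labels]
    lo, hi = 0.0, 255.0
    if lv.inverted:
        pixels = hi - pixels
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, pixels.shape).astype(np.float32)
        pixels = np.clip(pixels, lo, hi)
    image = GrayImage(pixels.astype(np.float32), (lo, hi), spec.section_kind)

    # fragments sit inside the cavity, so the full cavity region is the
    # pre-blockage cavity mask; its pixels are split between CAVITY and BLOCKAGE
    blockage_area = int(blockage.sum())
    cavity_area = int(cavity_mask.sum())
    truth = PhantomTruth(
        cavity_area_px=cavity_area,
        blockage_area_px=blockage_area,
        blocked=blockage_area > 0,
        spec=spec,
        labels=labels,
    )
    return image, truth


def _place_blockage(cavity_mask: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Drop 1-5 convex bright fragments wholly inside the cavity.

    Fragments keep a >=3 px dark margin from the cavity boundary and from
    each other, so they read as enclosed holes of the dark cavity component.
    Total fragment area approximates ``fraction`` of the cavity area (it can
    fall short when the cavity is too small to host the margin).
    """
    frag = np.zeros_like(cavity_mask)
    target = fraction * cavity_mask.sum()
    if target < 1 or not cavity_mask.any():
        return frag
    margin = 3.0
    n_frag = int(rng.integers(1, 6))
    areas = rng.dirichlet(np.ones(n_frag)) * target
    areas = np.maximum(areas, 12.0)
    areas *= target / areas.sum()
    for area in areas:
        radius = math.sqrt(area / math.pi)
        for _ in range(12):
            free = cavity_mask & ~ndimage.binary_dilation(
                frag, structure=_disk_struct(margin)
            )
            edt = ndimage.distance_transform_edt(free)
            candidates = np.argwhere(edt > radius + margin)
            if len(candidates):
                r0, c0 = candidates[rng.integers(len(candidates))]
                yy, xx = np.ogrid[0 : cavity_mask.shape[0], 0 : cavity_mask.shape[1]]
                frag |= (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2
                break
            radius *= 0.8  # shrink until it fits; give up below ~2 px
            if radius < 2.0:
                break
    return frag & cavity_mask


def _place_ruptures(labels, cavity_mask, count: int, rng) -> np.ndarray:
    """Small dark dots in the pulp, kept >=12 px away from the cavity."""
    out = np.zeros(labels.shape, dtype=bool)
    if count <= 0:
        return out
    pulp = labels == PULP
    far_from_cavity = ndimage.distance_transform_edt(~cavity_mask) > 12
    for _ in range(count):
        radius = rng.uniform(1.0, 2.5)
        allowed = pulp & far_from_cavity
        edt = ndimage.distance_transform_edt(allowed)
        candidates = np.argwhere(edt > radius + 1)
        if not len(candidates):
            break
        r0, c0 = candidates[rng.integers(len(candidates))]
        yy, xx = np.ogrid[0 : labels.shape[0], 0 : labels.shape[1]]
        out |= ((yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2) & pulp
    return out


def _disk_struct(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return np.hypot(yy, xx) <= radius


def add_noise(image: GrayImage, noise_sd: float, seed: int) -> GrayImage:
    """Additive zero-mean Gaussian noise, clipped to the valid range.

    Deterministic for a given seed; ``noise_sd=0`` returns the input image
    unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return image
    rng = np.random.default_rng(seed)
    lo, hi = image.value_range
    noisy = image.pixels.astype(np.float32) + rng.normal(
        0.0, noise_sd, image.pixels.shape
    ).astype(np.float32)
    return GrayImage(np.clip(noisy, lo, hi), image.value_range, image.section_kind)


def generate_pair(
    spec: PhantomSpec,
    deformation_mm: float,
    damage_model: DamageModel | None = None,
) -> PhantomPair:
    """Generate a matched pre/post compression pair.

    The pre-compression section is ``spec`` with no blockage.  The
    post-compression section scales both cavity semi-axes by the square root
    of the model's area factor (so the cavity area grows by that factor up
    to rasterisation) and adds the model's blockage fraction.  Both sections
    share the spec seed, so the cavity grows self-similarly; the recorded
    ``true_damage_rate`` is computed from the two exact truths, not from the
    model.
    """
    if deformation_mm < 0:
        raise ValueError("deformation must be non-negative")
    model = damage_model if damage_model is not None else DamageModel()
    scale = model.area_scale(deformation_mm)
    if scale < 0:
        raise ValueError("damage model produced a negative area scale")
    k = math.sqrt(scale)
    a, b = spec.cavity_radius

    pre_spec = replace(spec, blockage_fraction=0.0)
    post_spec = replace(
        spec,
        cavity_radius=(a * k, b * k),
        blockage_fraction=model.blockage_fraction(deformation_mm),
    )
    pre_image, pre_truth = generate_section(pre_spec)
    post_image, post_truth = generate_section(post_spec)
    if pre_truth.cavity_area_px == 0:
        raise GeometryError("pre-compression cavity area is zero; damage rate undefined")
    rate = (
        (post_truth.cavity_area_px - pre_truth.cavity_area_px)
        / pre_truth.cavity_area_px
        * 100.0
    )
    return PhantomPair(
        pre_image=pre_image,
        pre_truth=pre_truth,
        post_image=post_image,
        post_truth=post_truth,
        deformation_mm=float(deformation_mm),
        true_damage_rate=float(rate),
    )


def random_spec(
    seed: int,
    image_size: int = 512,
    section_kind: str = "cross",
    blockage_fraction: float = 0.0,
    rupture_count: int = 0,
    noise_sd: float = 0.0,
) -> PhantomSpec:
    """A spec with seeded fruit-to-fruit geometric variation.

    Fruit radius, peel thickness, cavity size and aspect vary in realistic
    ranges so a suite of phantoms exercises the pipeline across individuals,
    the way a batch of scanned fruits would.
    """
    rng = np.random.default_rng(seed)
    scale = image_size / 512.0
    fruit_radius = rng.uniform(200.0, 232.0) * scale
    peel = rng.uniform(14.0, 22.0) * scale
    a = rng.uniform(34.0, 46.0) * scale
    aspect = rng.uniform(0.75, 0.95)
    return PhantomSpec(
        image_size=image_size,
        fruit_radius=fruit_radius,
        peel_thickness=peel,
        cavity_radius=(a, a * aspect),
        n_segments=int(rng.integers(8, 12)),
        lobe_amplitude=rng.uniform(0.04, 0.10),
        lobe_count=int(rng.integers(4, 7)),
        blockage_fraction=blockage_fraction,
        rupture_count=rupture_count,
        noise_sd=noise_sd,
        section_kind=section_kind,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_truth_table(truths, path, section_kinds=None) -> None:
    """Write a CSV ground-truth table (one row per generated section)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "section_kind", "cavity_area_px", "blockage_area_px", "blocked", "seed"]
        )
        for i, t in enumerate(truths):
            writer.writerow(
                [i, t.spec.section_kind, t.cavity_area_px, t.blockage_area_px,
                 t.blocked, t.spec.seed]
            )
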