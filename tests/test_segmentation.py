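"""Stage-by-stage checks of the cavity-extraction pipeline."""

import dataclasses

import numpy as np
import pytest

from pulpscan import (
    BinaryImage,
    EmptyMaskError,
    NoCavityError,
    SeedPointError,
    SegmentationConfig,
    StageError,
    apply_mask,
    binarize,
    build_mask,
    classify_blockage,
    connectivity_selem,
    dilate,
    extract_cavity_area,
    fill_by_region_growing,
    generate_section,
    isolate_cavity,
    random_spec,
    refine,
)
from pulpscan import phantom as ph
from pulpscan.segmentation import disk_selem

from _oracles import brute_dilate, brute_erode, brute_otsu_classes
from conftest import as_gray


class TestBinarize:
    def test_fixed_threshold_above_constant_gives_background(self):
        img = as_gray(np.full((6, 6), 50.0))
        out = binarize(img, "fixed", 60.0)
        assert not out.pixels.any()

    def test_otsu_separates_two_levels_like_exhaustive_search(self):
        rng = np.random.default_rng(4)
        arr = rng.choice([10.0, 200.0], size=(4, 4))
        arr[0, 0], arr[1, 1] = 10.0, 200.0  # ensure both classes present
        out = binarize(as_gray(arr), "otsu")
        assert np.array_equal(out.pixels, arr == 200.0)
        assert np.array_equal(out.pixels, brute_otsu_classes(arr))

    def test_fixed_threshold_at_max_strict_comparison(self):
        arr = np.arange(16.0).reshape(4, 4)
        out = binarize(as_gray(arr), "fixed", float(arr.max()))
        assert not out.pixels.any()

    def test_constant_image_otsu_warns_all_background(self):
        img = as_gray(np.full((8, 8), 42.0))
        with pytest.warns(RuntimeWarning, match="constant image"):
            out = binarize(img, "otsu")
        assert not out.pixels.any()

    def test_threshold_recorded(self):
        arr = np.where(np.eye(8, dtype=bool), 200.0, 10.0)
        out = binarize(as_gray(arr), "otsu")
        assert out.threshold is not None and 10.0 < out.threshold < 200.0


class TestBuildMask:
    def test_radius_zero_identity_on_solid_component(self):
        fg = np.zeros((8, 8), bool)
        fg[2:5, 3:6] = True
        out = build_mask(BinaryImage(fg), 0.0)
        assert np.array_equal(out.pixels, fg)

    def test_square_element_erosion_matches_set_definition(self):
        fg = np.ones((5, 5), bool)
        out = build_mask(BinaryImage(fg), 1.0, selem=np.ones((3, 3), bool))
        expected = np.zeros((5, 5), bool)
        expected[1:4, 1:4] = True
        assert np.array_equal(out.pixels, expected)
        assert np.array_equal(out.pixels, brute_erode(fg, np.ones((3, 3), bool)))

    def test_only_largest_component_kept(self):
        fg = np.zeros((20, 20), bool)
        fg[2:12, 2:7] = True  # 50 px
        fg[15:17, 10:15] = True  # 10 px
        out = build_mask(BinaryImage(fg), 0.0)
        expected = np.zeros_like(fg)
        expected[2:12, 2:7] = True
        assert np.array_equal(out.pixels, expected)

    def test_holes_inside_largest_component_are_filled(self):
        fg = np.zeros((12, 12), bool)
        fg[2:10, 2:10] = True
        fg[5:7, 5:7] = False  # interior hole (the cavity analogue)
        out = build_mask(BinaryImage(fg), 0.0)
        assert out.pixels[5, 5]

    def test_oversized_core_annihilates(self):
        fg = np.zeros((10, 10), bool)
        fg[4:7, 4:7] = True
        with pytest.raises(EmptyMaskError):
            build_mask(BinaryImage(fg), 5.0)


class TestApplyMask:
    def test_full_mask_identity(self):
        img = as_gray(np.arange(16.0).reshape(4, 4))
        out = apply_mask(img, BinaryImage(np.ones((4, 4), bool)))
        assert np.array_equal(out.pixels, img.pixels)

    def test_empty_mask_zeroes(self):
        img = as_gray(np.arange(16.0).reshape(4, 4))
        out = apply_mask(img, BinaryImage(np.zeros((4, 4), bool)))
        assert not out.pixels.any()

    def test_single_pixel_mask(self):
        img = as_gray(np.arange(30.0).reshape(5, 6))
        mask = np.zeros((5, 6), bool)
        mask[2, 3] = True
        out = apply_mask(img, BinaryImage(mask))
        assert out.pixels[2, 3] == img.pixels[2, 3]
        assert out.pixels.sum() == img.pixels[2, 3]

    def test_dimension_mismatch_rejected(self):
        img = as_gray(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            apply_mask(img, BinaryImage(np.ones((5, 5), bool)))


class TestIsolateCavity:
    def test_phantom_candidate_equals_cavity_label_set(self, small_spec, default_config):
        spec = dataclasses.replace(small_spec, rupture_count=3)
        image, truth = generate_section(spec)
        binary = binarize(image)
        mask = build_mask(binary, default_config.core_radius_for("cross"))
        masked = apply_mask(image, mask)
        candidate = isolate_cavity(masked, default_config)
        assert np.array_equal(candidate.pixels, truth.labels == ph.CAVITY)

    def test_uniformly_bright_raises_no_cavity(self, default_config):
        img = as_gray(np.full((32, 32), 200.0))
        with pytest.raises(NoCavityError):
            isolate_cavity(img, default_config)

    def test_central_component_beats_larger_peripheral_one(self, default_config):
        arr = np.full((64, 64), 200.0)
        arr[27:37, 27:37] = 5.0  # central, 100 px
        arr[2:22, 2:22] = 5.0  # peripheral, 400 px
        candidate = isolate_cavity(as_gray(arr), default_config)
        assert candidate.pixels[32, 32]
        assert not candidate.pixels[10, 10]
        assert candidate.area == 100


class TestRefine:
    def test_zero_radii_identity(self):
        fg = np.zeros((9, 9), bool)
        fg[3:6, 3:6] = True
        cfg = SegmentationConfig(refine_dilate_radius=0.0, refine_erode_radius=0.0)
        out = refine(BinaryImage(fg), cfg)
        assert np.array_equal(out.pixels, fg)

    def test_single_pixel_gap_closed_and_matches_oracle(self):
        # 11x11 ring (2-px wall) with a 1-px gap through the wall; closing
        # reconnects the boundary so the interior becomes enclosed again
        from scipy import ndimage

        ring = np.zeros((11, 11), bool)
        ring[2:9, 2:9] = True
        ring[4:7, 4:7] = False
        ring[2:4, 5] = False  # the gap
        assert not (ndimage.binary_fill_holes(ring) & ~ring)[5, 5]  # leaks before
        cfg = SegmentationConfig(refine_dilate_radius=1.5, refine_erode_radius=1.5)
        out = refine(BinaryImage(ring), cfg)
        expected = brute_erode(brute_dilate(ring, disk_selem(1.5)), disk_selem(1.5))
        assert np.array_equal(out.pixels, expected)
        filled = ndimage.binary_fill_holes(out.pixels)
        assert (filled & ~out.pixels)[5, 5]  # interior enclosed after closing

    def test_dilate_isolated_pixel_8_connectivity(self):
        px = np.zeros((5, 5), bool)
        px[2, 2] = True
        out = dilate(px, connectivity_selem(8))
        expected = np.zeros((5, 5), bool)
        expected[1:4, 1:4] = True
        assert np.array_equal(out, expected)

    def test_refinement_that_empties_raises(self):
        fg = np.zeros((9, 9), bool)
        fg[4, 4] = True
        cfg = SegmentationConfig(refine_dilate_radius=0.0, refine_erode_radius=3.0)
        with pytest.raises(EmptyMaskError):
            refine(BinaryImage(fg), cfg)


class TestRegionGrowingFill:
    def test_unblocked_component_unchanged(self):
        fg = np.zeros((15, 15), bool)
        fg[5:10, 5:10] = True
        cfg = SegmentationConfig()
        out = fill_by_region_growing(BinaryImage(fg), cfg)
        assert np.array_equal(out.pixels, fg)

    def test_ring_with_bright_blob_filled(self):
        # dark ring enclosing a 3x3 (9 px) bright blob
        ring = np.zeros((15, 15), bool)
        ring[4:11, 4:11] = True
        ring[6:9, 6:9] = False  # 9-px enclosed hole
        cfg = SegmentationConfig(seed_rule="explicit", seed_point=(7, 7))
        out = fill_by_region_growing(BinaryImage(ring), cfg)
        assert out.area == ring.sum() + 9

    def test_seed_on_background_corner_raises(self):
        fg = np.zeros((15, 15), bool)
        fg[5:10, 5:10] = True
        cfg = SegmentationConfig(seed_rule="explicit", seed_point=(0, 0))
        with pytest.raises(SeedPointError):
            fill_by_region_growing(BinaryImage(fg), cfg)


class TestClassifyBlockage:
    def test_phantom_without_blockage_is_unblocked(self, small_spec, default_config):
        image, _ = generate_section(small_spec)
        result = extract_cavity_area(image, default_config)
        assert result.blocked is False

    def test_phantom_with_blockage_detected(self, small_spec, default_config):
        spec = dataclasses.replace(small_spec, blockage_fraction=0.2)
        image, truth = generate_section(spec)
        assert truth.blocked
        result = extract_cavity_area(image, default_config)
        assert result.blocked is True

    def test_enclosed_area_exactly_at_threshold_is_unblocked(self):
        # 10x10 filled cavity (100 px) with a single-pixel hole: 1 == 0.01*100
        cand = np.zeros((14, 14), bool)
        cand[2:12, 2:12] = True
        cand[6, 6] = False
        cfg = SegmentationConfig(blockage_area_fraction_threshold=0.01)
        masked = as_gray(np.where(cand, 5.0, 200.0))
        assert classify_blockage(BinaryImage(cand), masked, cfg) is False


class TestExtractCavityArea:
    def test_unblocked_recovery_within_two_percent(self, small_spec, default_config):
        image, truth = generate_section(small_spec)
        result = extract_cavity_area(image, default_config)
        assert abs(result.area_px - truth.cavity_area_px) <= 0.02 * truth.cavity_area_px
        assert list(result.intermediates) == [
            "A_binarize", "B_mask", "C_masked", "D_candidate", "EF_refined", "G_filled",
        ]

    def test_blocked_recovery_within_three_percent(self, small_spec, default_config):
        spec = dataclasses.replace(small_spec, blockage_fraction=0.2, rupture_count=4)
        image, truth = generate_section(spec)
        result = extract_cavity_area(image, default_config)
        assert abs(result.area_px - truth.cavity_area_px) <= 0.03 * truth.cavity_area_px

    def test_blank_image_raises_no_cavity(self, default_config):
        with pytest.warns(RuntimeWarning):
            with pytest.raises((NoCavityError, StageError)):
                extract_cavity_area(as_gray(np.zeros((64, 64))), default_config)

    def test_stage_error_names_failing_stage(self, default_config):
        # bright frame too thin to survive the erosion core -> stage B fails
        arr = np.zeros((40, 40))
        arr[18:22, 18:22] = 200.0
        with pytest.raises(StageError) as err:
            extract_cavity_area(as_gray(arr), default_config)
        assert err.value.stage == "B_mask"

    def test_idempotent_on_rendered_cavity_mask(self, small_spec, default_config):
        image, _ = generate_section(small_spec)
        first = extract_cavity_area(image, default_config)
        rendered = as_gray(np.where(first.filled_mask.pixels, 10.0, 160.0))
        second = extract_cavity_area(rendered, default_config)
        assert second.area_px == first.area_px

    def test_noise_robustness_on_phantom_suite(self, default_config):
        # noise sd at 5% of the pulp-cavity contrast moves areas by <= 5%
        for k in range(5):
            spec = random_spec(500 + k, image_size=256)
            clean, _ = generate_section(spec)
            noisy = generate_section(dataclasses.replace(spec, noise_sd=7.5))[0]
            a0 = extract_cavity_area(clean, default_config).area_px
            a1 = extract_cavity_area(noisy, default_config).area_px
            assert abs(a1 - a0) <= 0.05 * a0

    def test_longitudinal_section_uses_larger_core_and_recovers(self, default_config):
        spec = random_spec(77, section_kind="longitudinal")
        image, truth = generate_section(spec)
        result = extract_cavity_area(image, default_config)
        assert abs(result.area_px - truth.cavity_area_px) <= 0.02 * truth.cavity_area_px
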