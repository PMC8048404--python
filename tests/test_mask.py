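"""The five-step automatic masking routine."""

import warnings

import numpy as np
import pytest
from skimage import draw, filters, measure

import scanforge as sf
from scanforge.mask import (
    EmptyMaskWarning,
    MaskParams,
    apply_cutout,
    clean_mask,
    detect_outline,
    enhance,
    largest_shape_mask,
    mask_pipeline,
    remove_infill,
)
from conftest import iou


class TestEnhance:
    def test_constant_image_stays_constant(self):
        out = enhance(np.full((128, 128), 130, np.uint8))
        assert np.ptp(out) == 0

    def test_clahe_increases_global_contrast(self):
        rng = np.random.default_rng(0)
        low = (120 + 10 * rng.standard_normal((256, 256))).clip(0, 255)
        low = low.astype(np.uint8)
        out = enhance(low)
        spread = lambda im: np.percentile(im, 99) - np.percentile(im, 1)
        assert spread(out) > spread(low)

    def test_median_step_removes_salt_and_pepper(self):
        rng = np.random.default_rng(1)
        base = (120 + 30 * np.sin(np.linspace(0, 8 * np.pi, 256)))[None, :]
        base = (base * np.ones((256, 1))).astype(np.uint8)
        corrupted = base.copy()
        idx = rng.choice(base.size, 600, replace=False)
        corrupted.ravel()[idx[:300]] = 255
        corrupted.ravel()[idx[300:]] = 0
        med = filters.median(corrupted, footprint=np.ones((5, 5), bool))
        recovered = np.abs(
            med.ravel()[idx].astype(int) - base.ravel()[idx].astype(int)
        ) < 30
        assert recovered.mean() >= 0.99

    def test_output_same_dimensions(self, specimen_fixture):
        edof, _ = specimen_fixture
        assert enhance(edof).shape == edof.pixels.shape[:2]


class TestDetectOutline:
    def test_constant_image_gives_zero_edges(self):
        edges = detect_outline(np.full((64, 64), 50, np.uint8))
        assert np.all(edges == 0)

    def test_disk_boundary_concentrates_edge_mass(self):
        img = np.full((256, 256), 200, np.uint8)
        rr, cc = draw.disk((128, 128), 60)
        img[rr, cc] = 60
        edges = detect_outline(enhance(img))
        yy, xx = np.mgrid[0:256, 0:256]
        annulus = np.abs(np.hypot(yy - 128, xx - 128) - 60) <= 2.5
        assert edges[annulus].sum() / edges.sum() >= 0.90
        assert edges.max() <= 1.0 and edges.min() >= 0.0

    def test_nested_contours_both_detected(self):
        img = np.full((256, 256), 200, np.uint8)
        rr, cc = draw.disk((128, 128), 70)
        img[rr, cc] = 60
        rr, cc = draw.disk((128, 128), 35)
        img[rr, cc] = 200  # inner background
        edges = detect_outline(enhance(img))
        yy, xx = np.mgrid[0:256, 0:256]
        r = np.hypot(yy - 128, xx - 128)
        outer = edges[np.abs(r - 70) <= 3].max()
        inner = edges[np.abs(r - 35) <= 3].max()
        assert outer > 0.3 and inner > 0.3

    def test_forest_without_model_is_configuration_error(self):
        with pytest.raises(sf.ConfigurationError):
            detect_outline(np.zeros((8, 8), np.uint8), detector="forest")


class TestLargestShapeMask:
    def test_keeps_only_largest_disk(self):
        edges = np.zeros((200, 200))
        rr, cc = draw.circle_perimeter(60, 60, 40)
        edges[rr, cc] = 1.0
        rr, cc = draw.circle_perimeter(150, 150, 15)
        edges[rr, cc] = 1.0
        mask = largest_shape_mask(edges, 0.5)
        assert mask[60, 60] and not mask[150, 150]

    def test_blank_edges_warn_and_return_empty(self):
        with pytest.warns(EmptyMaskWarning):
            mask = largest_shape_mask(np.zeros((64, 64)), 0.5)
        assert not mask.any()

    def test_enclosed_background_filled_at_this_stage(self, specimen_fixture):
        edof, gt_mask = specimen_fixture
        edges = detect_outline(enhance(edof))
        mask = largest_shape_mask(edges, MaskParams().edge_threshold)
        # filling closes the enclosed hole, so area exceeds the true mask
        assert mask.sum() >= gt_mask.sum()


class TestRemoveInfill:
    @staticmethod
    def _ring_fixture():
        img = np.full((300, 300), 195, np.uint8)
        mask = np.zeros((300, 300), bool)
        rr, cc = draw.disk((150, 150), 70)
        mask[rr, cc] = True
        inner = np.zeros_like(mask)
        rr, cc = draw.disk((150, 150), 40)
        inner[rr, cc] = True
        img[mask & ~inner] = 60
        return img, mask, inner

    def test_enclosed_disc_flipped_ring_kept(self):
        img, mask, inner = self._ring_fixture()
        out = remove_infill(mask, img)
        assert not out[inner].any()
        assert out[mask & ~inner].all()

    def test_mask_without_holes_unchanged(self):
        img = np.full((300, 300), 195, np.uint8)
        solid = np.zeros((300, 300), bool)
        rr, cc = draw.disk((150, 150), 70)
        solid[rr, cc] = True
        img[solid] = 60
        out = remove_infill(solid, img)
        assert (out != solid).mean() <= 0.001

    def test_all_background_mask_unchanged(self):
        img = np.full((64, 64), 195, np.uint8)
        empty = np.zeros((64, 64), bool)
        assert not remove_infill(empty, img).any()

    def test_never_flips_background_to_foreground(self, specimen_fixture):
        edof, _ = specimen_fixture
        mask = np.zeros(edof.pixels.shape[:2], bool)
        mask[100:200, 100:200] = True
        out = remove_infill(mask, edof)
        assert not out[~mask].any()


class TestCleanMask:
    def test_speckles_removed_big_component_kept(self):
        mask = np.zeros((1000, 1000), bool)
        mask[:100, :100] = True  # 10,000 px
        rng = np.random.default_rng(1)
        for _ in range(10):
            y, x = rng.integers(200, 900, 2)
            mask[y, x:x + 5] = True  # 5 px speckles
        out = clean_mask(mask, MaskParams(min_component_fraction=1e-4))
        assert measure.label(out, connectivity=2).max() == 1
        assert out[:100, :100].all()

    def test_component_at_exact_threshold_retained(self):
        # 100x100 image, fraction 5e-3 -> min area 50 px
        mask = np.zeros((100, 100), bool)
        mask[:40, :40] = True  # dominant component
        mask[60:70, 60:65] = True  # exactly 50 px
        out = clean_mask(mask, MaskParams(min_component_fraction=5e-3))
        assert out[60:70, 60:65].all()

    def test_small_holes_filled(self):
        mask = np.ones((200, 200), bool)
        mask[50:52, 50:52] = False  # 4 px pinhole
        out = clean_mask(mask, MaskParams(min_component_fraction=1e-3))
        assert out.all()

    def test_clean_single_component_unchanged(self, specimen_fixture):
        _, gt_mask = specimen_fixture
        cleaned = clean_mask(gt_mask)
        assert iou(cleaned, gt_mask) > 0.999

    def test_idempotent(self, specimen_fixture):
        edof, _ = specimen_fixture
        mask, _ = mask_pipeline(edof)
        once = clean_mask(mask)
        assert np.array_equal(clean_mask(once), once)


class TestApplyCutout:
    def test_full_mask_zero_mode_is_identity(self, specimen_fixture):
        edof, _ = specimen_fixture
        full = np.ones(edof.pixels.shape[:2], bool)
        assert np.array_equal(apply_cutout(edof, full, "zero"), edof.pixels)

    def test_empty_mask_zero_mode_all_zero(self, specimen_fixture):
        edof, _ = specimen_fixture
        empty = np.zeros(edof.pixels.shape[:2], bool)
        assert not apply_cutout(edof, empty, "zero").any()

    def test_foreground_pixels_untouched(self, specimen_fixture):
        edof, gt_mask = specimen_fixture
        zero = apply_cutout(edof, gt_mask, "zero")
        assert np.array_equal(zero[gt_mask], edof.pixels[gt_mask])
        alpha = apply_cutout(edof, gt_mask, "alpha")
        # grey input is replicated to RGB before the alpha channel is added
        assert np.array_equal(alpha[gt_mask][:, 0], edof.pixels[gt_mask])

    def test_alpha_channel_encodes_mask(self, specimen_fixture):
        edof, gt_mask = specimen_fixture
        out = apply_cutout(edof, gt_mask, "alpha")
        assert out.shape[-1] == 4
        assert np.array_equal(out[..., -1] > 0, gt_mask)

    def test_dimension_mismatch_rejected(self, specimen_fixture):
        edof, _ = specimen_fixture
        with pytest.raises(sf.InvalidInputError):
            apply_cutout(edof, np.zeros((4, 4), bool), "zero")


class TestMaskPipeline:
    def test_clean_fixture_high_iou(self, specimen_fixture):
        edof, gt_mask = specimen_fixture
        mask, _ = mask_pipeline(edof)
        assert iou(mask, gt_mask) >= 0.95

    def test_noisy_fixture_iou(self):
        spec = sf.FixtureSpec(seed=11, shape=(512, 512), noise_sigma=0.02)
        edof, gt_mask = sf.make_specimen_edof(spec)
        mask, _ = mask_pipeline(edof)
        assert iou(mask, gt_mask) >= 0.93

    def test_iou_degrades_monotonically_with_noise(self):
        ious = []
        for noise in (0.0, 0.02, 0.05):
            spec = sf.FixtureSpec(seed=11, shape=(512, 512), noise_sigma=noise)
            edof, gt_mask = sf.make_specimen_edof(spec)
            mask, _ = mask_pipeline(edof)
            ious.append(iou(mask, gt_mask))
        assert all(a >= b for a, b in zip(ious, ious[1:]))

    def test_deterministic(self, specimen_fixture):
        edof, _ = specimen_fixture
        m1, c1 = mask_pipeline(edof)
        m2, c2 = mask_pipeline(edof)
        assert np.array_equal(m1, m2) and np.array_equal(c1, c2)

    def test_background_only_image_warns_empty(self):
        flat = np.full((256, 256), 200, np.uint8)
        with pytest.warns(EmptyMaskWarning):
            mask, cutout = mask_pipeline(flat)
        assert not mask.any()
        assert not cutout.any()

    def test_foreground_values_never_altered(self, specimen_fixture):
        edof, _ = specimen_fixture
        mask, cutout = mask_pipeline(edof, cutout_mode="zero")
        assert np.array_equal(cutout[mask], edof.pixels[mask])
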