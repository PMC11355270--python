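"""Vessel enhancement, binarization and masking stages."""

import numpy as np
import pytest

from octaquant import (
    AnnulusSpec,
    BinaryMap,
    EnFaceImage,
    FAZAnnotation,
    ScanGeometry,
    binarize_flow_deficits,
    binarize_vessels,
    enhance_large_vessels,
    mask_faz,
    remove_cc_artifacts,
    segment_large_vessels,
)
from octaquant.errors import ConfigError, DegenerateInputError, ValidationError
from octaquant.vessel_processing import VesselnessParams, VesselnessResponse


def slab(pixels, kind, geometry):
    return EnFaceImage(np.asarray(pixels, dtype=np.uint8), kind, geometry)


class TestEnhanceLargeVessels:
    def test_bar_responds_above_background(self, bar_image):
        img, bar = bar_image
        resp = enhance_large_vessels(img).response
        centerline = np.zeros_like(bar)
        centerline[122:124, 20:225] = True
        background = ~np.zeros_like(bar)
        background[110:136, :] = False  # keep clear of the bar's halo
        assert resp[centerline].mean() > 3 * resp[background].mean()

    def test_constant_image_gives_zero_response(self, geometry):
        img = slab(np.full((245, 245), 77), "SCP", geometry)
        resp = enhance_large_vessels(img).response
        assert np.all(resp < 1e-6)

    def test_orientation_isotropy(self, bar_image, geometry):
        img, bar = bar_image
        resp_h = enhance_large_vessels(img).response
        img_v = slab(img.pixels.T, "SCP", geometry)
        resp_v = enhance_large_vessels(img_v).response
        on_h = resp_h[bar].mean()
        on_v = resp_v[bar.T].mean()
        assert on_v == pytest.approx(on_h, rel=0.05)

    def test_rejects_non_scp(self, geometry):
        img = slab(np.zeros((245, 245)), "DCP", geometry)
        with pytest.raises(ValidationError):
            enhance_large_vessels(img)

    def test_empty_parameter_lists_rejected(self):
        with pytest.raises(ConfigError):
            VesselnessParams(hessian_scales_px=())
        with pytest.raises(ConfigError):
            VesselnessParams(n_orientations=0)


class TestSegmentLargeVessels:
    def test_bar_recovered(self, bar_image):
        img, bar = bar_image
        resp = enhance_large_vessels(img)
        mask = segment_large_vessels(resp).mask
        # interior of the bar, away from end effects
        core = np.zeros_like(bar)
        core[120:126, 10:235] = True
        assert mask[core].mean() >= 0.80
        assert mask[~bar & (np.abs(np.arange(245) - 122)[:, None] > 15)].mean() <= 0.02

    def test_zero_response_gives_empty_mask(self):
        resp = VesselnessResponse(np.zeros((64, 64)), VesselnessParams())
        assert segment_large_vessels(resp).count == 0

    def test_two_parallel_bars_two_components(self, geometry):
        from scipy import ndimage

        pixels = np.full((245, 245), 20, dtype=np.uint8)
        pixels[60:66, :] = 230
        pixels[180:186, :] = 230
        resp = enhance_large_vessels(slab(pixels, "SCP", geometry))
        mask = segment_large_vessels(resp).mask
        _, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 2

    def test_monotone_in_quantile_before_size_filter(self, bar_image):
        img, _ = bar_image
        resp = enhance_large_vessels(img)
        masks = [
            segment_large_vessels(resp, quantile=q, min_size_px=1, close_radius_px=0).mask
            for q in (0.85, 0.92, 0.97)
        ]
        assert (masks[1] & ~masks[0]).sum() == 0
        assert (masks[2] & ~masks[1]).sum() == 0


class TestBinarizeVessels:
    def test_two_level_image_splits_at_mean(self, geometry):
        pixels = np.zeros((245, 245), dtype=np.uint8)
        pixels[:, :122] = 200  # mean lies strictly between 0 and 200
        mask = binarize_vessels(slab(pixels, "SCP", geometry)).mask
        assert np.array_equal(mask, pixels == 200)

    def test_constant_image_is_all_vessel(self, geometry):
        mask = binarize_vessels(slab(np.full((245, 245), 13), "DCP", geometry)).mask
        assert mask.all()

    def test_affine_intensity_invariance(self, geometry):
        rng = np.random.default_rng(3)
        base = rng.integers(10, 100, (245, 245))
        m1 = binarize_vessels(slab(base, "SCP", geometry)).mask
        m2 = binarize_vessels(slab(2 * base + 10, "SCP", geometry)).mask
        assert np.array_equal(m1, m2)

    def test_rejects_cc(self, geometry):
        with pytest.raises(ValidationError):
            binarize_vessels(slab(np.zeros((245, 245)), "CC", geometry))


class TestMaskFAZ:
    def square_faz(self, side_mm=1.0, layer="superficial"):
        h = side_mm / 2
        return FAZAnnotation(np.array([[-h, -h], [h, -h], [h, h], [-h, h]]), layer)

    def test_vessel_count_drops_by_rasterized_area(self, geometry):
        from octaquant.vessel_processing import rasterize_polygon

        full = BinaryMap(np.ones((245, 245), bool), "vessels", "SCP")
        faz = self.square_faz()
        masked = mask_faz(full, faz, geometry)
        inside = rasterize_polygon(faz, geometry)
        assert full.count - masked.count == inside.sum()
        # ~1 mm^2 of a 3x3 mm field at 245 px: (245/3)^2 pixels up to rasterization
        assert inside.sum() == pytest.approx((245 / 3.0) ** 2, rel=0.02)

    def test_empty_mask_stays_empty(self, geometry):
        empty = BinaryMap(np.zeros((245, 245), bool), "vessels", "SCP")
        assert mask_faz(empty, self.square_faz(), geometry).count == 0

    def test_polygon_outside_field_is_identity(self, geometry):
        vessels = BinaryMap(np.ones((245, 245), bool), "vessels", "SCP")
        far = FAZAnnotation(np.array([[10, 10], [11, 10], [11, 11], [10, 11]]), "superficial")
        with pytest.warns(UserWarning):
            out = mask_faz(vessels, far, geometry)
        assert np.array_equal(out.mask, vessels.mask)

    def test_idempotent_and_disjoint_commute(self, geometry):
        rng = np.random.default_rng(0)
        vessels = BinaryMap(rng.random((245, 245)) > 0.5, "vessels", "SCP")
        a = self.square_faz(0.6)
        b = FAZAnnotation(self.square_faz(0.4).vertices + 1.0, "superficial")
        once = mask_faz(vessels, a, geometry)
        assert np.array_equal(mask_faz(once, a, geometry).mask, once.mask)
        ab = mask_faz(mask_faz(vessels, a, geometry), b, geometry)
        ba = mask_faz(mask_faz(vessels, b, geometry), a, geometry)
        assert np.array_equal(ab.mask, ba.mask)

    def test_layer_slab_mismatch(self, geometry):
        vessels = BinaryMap(np.ones((245, 245), bool), "vessels", "SCP")
        with pytest.raises(ValidationError):
            mask_faz(vessels, self.square_faz(layer="deep"), geometry)


class TestRemoveCCArtifacts:
    def test_empty_lv_mask_gives_empty_artifact(self, geometry):
        cc = slab(np.full((245, 245), 120), "CC", geometry)
        lv = BinaryMap(np.zeros((245, 245), bool), "large_vessels", "SCP")
        _, artifact = remove_cc_artifacts(cc, lv)
        assert artifact.count == 0

    def test_zero_dilation_is_identity(self, geometry):
        rng = np.random.default_rng(5)
        lv = BinaryMap(rng.random((245, 245)) < 0.10, "large_vessels", "SCP")
        cc = slab(np.full((245, 245), 120), "CC", geometry)
        _, artifact = remove_cc_artifacts(cc, lv, dilation_radius_px=0)
        assert np.array_equal(artifact.mask, lv.mask)

    def test_shadow_exclusion_raises_cc_mean(self, geometry):
        pixels = np.full((245, 245), 150, dtype=np.uint8)
        shadow = np.zeros((245, 245), bool)
        shadow[:, 100:120] = True
        pixels[shadow] = 40  # dark LV shadow
        cc = slab(pixels, "CC", geometry)
        _, artifact = remove_cc_artifacts(cc, BinaryMap(shadow, "large_vessels", "SCP"))
        clean_mean = pixels[~artifact.mask].mean()
        assert clean_mean > pixels.mean()

    def test_shape_mismatch(self, geometry):
        cc = slab(np.zeros((245, 245)), "CC", geometry)
        lv = BinaryMap(np.zeros((100, 100), bool), "large_vessels", "SCP")
        with pytest.raises(ValidationError):
            remove_cc_artifacts(cc, lv)


class TestBinarizeFlowDeficits:
    def test_bimodal_closed_form(self, geometry):
        # 95% at 180, 5% at 20: mu = 172, sigma = 34.87, threshold ~137.1
        n = 245 * 245
        k = int(round(0.05 * n))
        flat = np.full(n, 180, dtype=np.uint8)
        flat[:k] = 20
        rng = np.random.default_rng(7)
        rng.shuffle(flat)
        cc = slab(flat.reshape(245, 245), "CC", geometry)
        mask = binarize_flow_deficits(cc).mask
        assert np.array_equal(mask, cc.pixels == 20)

    def test_constant_image_has_no_deficits(self, geometry):
        cc = slab(np.full((245, 245), 99), "CC", geometry)
        assert binarize_flow_deficits(cc).count == 0

    def test_affine_equivariance(self, geometry):
        rng = np.random.default_rng(11)
        base = rng.integers(20, 110, (245, 245))
        m1 = binarize_flow_deficits(slab(base, "CC", geometry)).mask
        m2 = binarize_flow_deficits(slab(2 * base + 5, "CC", geometry)).mask
        assert np.array_equal(m1, m2)

    def test_all_artifact_degenerate(self, geometry):
        cc = slab(np.zeros((245, 245)), "CC", geometry)
        allmask = BinaryMap(np.ones((245, 245), bool), "artifact", "CC")
        with pytest.raises(DegenerateInputError):
            binarize_flow_deficits(cc, allmask)
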