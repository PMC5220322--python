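import numpy as np
import pytest

from isletdose.autoradiography import (
    MaskSet,
    SectionImage,
    analyze_section,
    dilate_islets,
    estimate_background,
    exocrine_mean,
    islet_fraction,
    islet_signal,
    register_masks,
    search_registration,
    uptake_ratio,
)
from isletdose.synthetic_data import SectionModel, gen_section


def _toy_masks(shape=(64, 64)):
    """Small hand-built section: one square islet in a rectangular tissue."""
    tissue = np.zeros(shape, dtype=bool)
    tissue[16:48, 16:48] = True
    labels = np.zeros(shape, dtype=np.int32)
    labels[28:36, 28:36] = 1
    regions = []
    for sl in ((slice(0, 6), slice(0, 6)), (slice(0, 6), slice(-6, None)), (slice(-6, None), slice(0, 6))):
        reg = np.zeros(shape, dtype=bool)
        reg[sl] = True
        regions.append(reg)
    return MaskSet(tissue, labels, tuple(regions))


def _toy_image(masks, islet=120.0, exocrine=20.0, background=5.0):
    px = np.full(masks.tissue_mask.shape, background)
    px[masks.tissue_mask] = background + exocrine
    px[masks.islet_labels > 0] = background + islet
    return SectionImage(px, pixel_size_um=20.0)


class TestMaskValidation:
    def test_islet_outside_tissue_rejected(self):
        masks = _toy_masks()
        labels = masks.islet_labels.copy()
        labels[0, 0] = 2
        with pytest.raises(ValueError, match="inside the tissue"):
            MaskSet(masks.tissue_mask, labels, masks.background_regions)

    def test_background_overlapping_tissue_rejected(self):
        masks = _toy_masks()
        bad = list(masks.background_regions)
        bad[0] = masks.tissue_mask.copy()
        with pytest.raises(ValueError, match="outside the tissue"):
            MaskSet(masks.tissue_mask, masks.islet_labels, tuple(bad))

    def test_exactly_three_background_regions(self):
        masks = _toy_masks()
        with pytest.raises(ValueError, match="three"):
            MaskSet(masks.tissue_mask, masks.islet_labels, masks.background_regions[:2])


class TestRegistration:
    def test_identity_leaves_masks_unchanged(self):
        masks = _toy_masks()
        image = _toy_image(masks)
        out = register_masks(image, masks, (1.0, 0.0))
        np.testing.assert_array_equal(out.tissue_mask, masks.tissue_mask)
        np.testing.assert_array_equal(out.islet_labels, masks.islet_labels)

    def test_zero_scale_rejected(self):
        masks = _toy_masks()
        with pytest.raises(ValueError):
            register_masks(_toy_image(masks), masks, (0.0, 10.0))

    def test_known_rotation_inverted_recovers_masks(self):
        img, masks, _ = gen_section(SectionModel(seed=5, transform=(1.0, 10.0)))
        img0, masks0, _ = gen_section(SectionModel(seed=5))
        reg = register_masks(img, masks, (1.0, -10.0))
        inter = (reg.tissue_mask & masks0.tissue_mask).sum()
        union = (reg.tissue_mask | masks0.tissue_mask).sum()
        assert inter / union > 0.95

    def test_grid_search_finds_true_transform(self):
        img, masks, _ = gen_section(SectionModel(seed=6, transform=(1.0, 8.0)))
        scale, rot = search_registration(
            img, masks, scales=[1.0], rotations_deg=np.arange(-12.0, 12.5, 2.0)
        )
        assert rot == pytest.approx(-8.0, abs=2.0)


class TestBackground:
    def test_constant_image_recovers_value(self):
        masks = _toy_masks()
        image = SectionImage(np.full((64, 64), 7.5), 20.0)
        assert estimate_background(image, masks) == 7.5

    def test_noisy_background_within_three_stderr(self):
        img, masks, truth = gen_section(SectionModel(seed=4))
        union = np.logical_or.reduce(masks.background_regions)
        est = estimate_background(img, masks)
        stderr = img.pixels[union].std(ddof=1) / np.sqrt(union.sum())
        assert abs(est - truth.background_level) < 3 * stderr


class TestDilation:
    def test_zero_radius_identity(self):
        masks = _toy_masks()
        out = dilate_islets(masks, 0.0, pixel_size_um=20.0)
        np.testing.assert_array_equal(out.islet_labels_dilated, masks.islet_labels)

    def test_area_monotone_in_radius(self):
        masks = _toy_masks()
        areas = [
            (dilate_islets(masks, r, 20.0).islet_labels_dilated > 0).sum()
            for r in (0.0, 40.0, 80.0, 120.0)
        ]
        assert all(a <= b for a, b in zip(areas, areas[1:]))
        assert areas[-1] > areas[0]

    def test_disjoint_islets_stay_disjoint(self):
        masks = _toy_masks()
        labels = masks.islet_labels.copy()
        labels[18:22, 18:22] = 2  # second islet well separated
        masks2 = MaskSet(masks.tissue_mask, labels, masks.background_regions)
        out = dilate_islets(masks2, 40.0, 20.0)
        assert set(np.unique(out.islet_labels_dilated)) == {0, 1, 2}
        # nearest-label expansion cannot merge labels
        assert ((out.islet_labels_dilated == 1) & (out.islet_labels_dilated == 2)).sum() == 0


class TestQuantification:
    def test_pure_background_image_gives_zero_exocrine(self):
        masks = dilate_islets(_toy_masks(), 0.0, 20.0)
        image = SectionImage(np.full((64, 64), 5.0), 20.0)
        assert exocrine_mean(image, masks, background=5.0) == 0.0

    def test_no_spillover_recovers_levels_exactly(self):
        masks = dilate_islets(_toy_masks(), 40.0, 20.0)
        image = _toy_image(masks, islet=120.0, exocrine=20.0, background=5.0)
        bg = estimate_background(image, masks)
        exo = exocrine_mean(image, masks, bg)
        per_islet, mean_val, clip, _ = islet_signal(image, masks, exo, bg)
        assert bg == 5.0 and exo == 20.0
        assert mean_val == pytest.approx(120.0, rel=1e-12)
        assert clip == 0.0
        assert uptake_ratio(per_islet, exo) == pytest.approx(6.0, rel=1e-12)

    def test_fully_dilated_tissue_rejected(self):
        masks = dilate_islets(_toy_masks(), 2000.0, 20.0)
        image = _toy_image(masks)
        with pytest.raises(ValueError, match="exocrine"):
            exocrine_mean(image, masks, 5.0)

    def test_zero_exocrine_ratio_rejected(self):
        with pytest.raises(ValueError):
            uptake_ratio(np.array([10.0]), 0.0)

    def test_ratio_scale_invariance(self):
        img, masks, truth = gen_section(SectionModel(seed=8, noise_scale=0.0))
        res1 = analyze_section(img, masks, psf_sigma_um=truth.psf_sigma_um)
        scaled = SectionImage(img.pixels * 3.7, img.pixel_size_um)
        res2 = analyze_section(scaled, masks, psf_sigma_um=truth.psf_sigma_um)
        assert res2.ratio_per_pixel == pytest.approx(res1.ratio_per_pixel, rel=1e-9)


class TestIsletFraction:
    def test_half_coverage(self):
        tissue = np.zeros((32, 32), dtype=bool)
        tissue[:, :16] = True
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[:, :8] = 1
        regions = []
        for i in range(3):
            reg = np.zeros((32, 32), dtype=bool)
            reg[i, 20] = True
            regions.append(reg)
        masks = MaskSet(tissue, labels, tuple(regions))
        assert islet_fraction(masks) == 0.5

    def test_no_islets_is_zero(self):
        masks = _toy_masks()
        empty = MaskSet(
            masks.tissue_mask, np.zeros_like(masks.islet_labels), masks.background_regions
        )
        assert islet_fraction(empty) == 0.0


class TestFullPipelineRecovery:
    def test_default_sections_recover_ratio_and_fraction(self):
        # three sections per animal, as in the source experiment
        ratios, fracs, true_fracs = [], [], []
        for seed in (1, 2, 3):
            img, masks, truth = gen_section(SectionModel(seed=seed))
            res = analyze_section(img, masks, psf_sigma_um=truth.psf_sigma_um)
            ratios.append(res.ratio_per_pixel / truth.uptake_ratio)
            fracs.append(res.islet_fraction)
            true_fracs.append(truth.islet_fraction)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)
        assert np.mean(fracs) == pytest.approx(np.mean(true_fracs), rel=0.15)

    def test_recovery_stable_over_dilation_radii(self):
        # spill-over capture saturates between 3 and 5 PSF sigmas
        img, masks, truth = gen_section(SectionModel(seed=9))
        ratios = [
            analyze_section(
                img, masks, psf_sigma_um=truth.psf_sigma_um, dilation_factor=k
            ).ratio_per_pixel
            for k in (3.0, 4.0, 5.0)
        ]
        assert max(ratios) / min(ratios) - 1 < 0.03
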