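import numpy as np
import pytest

from endodomain.metrics import (
    ColocResult,
    RatioResult,
    cell_area,
    fiber_length,
    interior_peripheral_ratio,
    mean_intensity_above_threshold,
    membrane_cytoplasm_ratio,
    microdomain_spread,
    thresholded_pearson,
)
from endodomain.roi import (
    AngularProfile,
    DiscROI,
    PixelImage,
    annulus_mask,
    circle_profile,
    default_n_samples,
    disc_mask,
    split_equal_area,
)
from endodomain.synthetic import generate_coelomocyte


def profile_of(values):
    values = np.asarray(values, dtype=float)
    return AngularProfile(
        angles_deg=np.arange(values.size) * (360.0 / values.size), intensities=values
    )


class TestResultTypes:
    def test_ratio_result_checks_log2_consistency(self):
        with pytest.raises(ValueError):
            RatioResult(ratio=2.0, log2_ratio=0.5, numerator_mean=2, denominator_mean=1,
                        n_regions_used=2)

    def test_coloc_result_needs_two_pixels(self):
        with pytest.raises(ValueError):
            ColocResult(pearson_r=0.5, n_pixels=1, threshold_ch1=0, threshold_ch2=0)


class TestMembraneCytoplasmRatio:
    def test_uniform_image_gives_unity(self, constant_image):
        img = constant_image(value=80.0)
        on = [DiscROI(center=(20, 20), radius_um=0.5)]
        off = [DiscROI(center=(44, 44), radius_um=0.5)]
        res = membrane_cytoplasm_ratio(img, on, off)
        assert res.ratio == pytest.approx(1.0)
        assert res.log2_ratio == pytest.approx(0.0)

    def test_constructed_two_to_one(self):
        values = np.full((64, 64), 100.0)
        values[10:20, 10:20] = 200.0
        img = PixelImage(values=values, pixel_size_um=0.1)
        on = [DiscROI(center=(14, 14), radius_um=0.3)]
        off = [DiscROI(center=(48, 48), radius_um=0.3)]
        res = membrane_cytoplasm_ratio(img, on, off)
        assert res.ratio == pytest.approx(2.0)
        assert res.log2_ratio == pytest.approx(1.0)

    def test_matches_masked_mean_oracle_on_noisy_scene(self, make_scene):
        spec = make_scene(noise_sd=10.0)
        channels, truth = generate_coelomocyte(spec)
        img = channels[0]
        on = [DiscROI(center=truth.rings[0].center, radius_um=1.5)]
        off = [DiscROI(center=(100, 140), radius_um=1.5)]
        res = membrane_cytoplasm_ratio(img, on, off)
        expected = (
            img.values[disc_mask(img, on[0])].mean()
            / img.values[disc_mask(img, off[0])].mean()
        )
        assert res.ratio == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_raises(self, constant_image):
        img = constant_image(value=0.0)
        on = [DiscROI(center=(20, 20), radius_um=0.5)]
        off = [DiscROI(center=(44, 44), radius_um=0.5)]
        with pytest.raises(ValueError, match="zero"):
            membrane_cytoplasm_ratio(img, on, off)

    def test_empty_disc_list_raises(self, constant_image):
        with pytest.raises(ValueError):
            membrane_cytoplasm_ratio(constant_image(), [], [])


class TestMicrodomainSpread:
    def test_all_above_gives_one(self):
        res = microdomain_spread([profile_of([5, 5, 5, 5])], threshold=1.0)
        assert res.fraction_above == 1.0

    def test_all_at_or_below_gives_zero(self):
        # strictly-above comparison: samples equal to the threshold do not count
        res = microdomain_spread([profile_of([1, 1, 0, 1])], threshold=1.0)
        assert res.fraction_above == 0.0

    def test_mean_over_profiles(self):
        res = microdomain_spread(
            [profile_of([2, 0, 0, 0]), profile_of([2, 2, 2, 0])], threshold=1.0
        )
        assert res.fraction_above == pytest.approx((0.25 + 0.75) / 2)
        assert res.n_endosomes_averaged == 2

    def test_rendered_arc_quarter_coverage(self, make_scene):
        channels, truth = generate_coelomocyte(make_scene())
        img, ring = channels[0], truth.rings[0]
        n = default_n_samples(img, ring)
        prof = circle_profile(img, ring, n)
        res = microdomain_spread([prof], threshold=200.0)
        assert abs(res.fraction_above - 0.25) <= 1.0 / n

    def test_monotone_in_threshold(self, make_scene):
        channels, truth = generate_coelomocyte(make_scene(noise_sd=15.0))
        prof = circle_profile(channels[0], truth.rings[0], 128)
        fracs = [
            microdomain_spread([prof], t).fraction_above for t in np.linspace(0, 400, 30)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_profile_list_raises(self):
        with pytest.raises(ValueError):
            microdomain_spread([], 1.0)


class TestInteriorPeripheralRatio:
    def _painted_cell(self, n_interior, v_interior, n_peripheral, v_peripheral):
        """Cell image whose above-threshold pixels are painted exactly."""
        img = PixelImage(values=np.full((201, 201), 10.0), pixel_size_um=0.1)
        cell = DiscROI(center=(100, 100), radius_um=8.0)
        interior, peripheral = split_equal_area(cell)
        vals = img.values
        for mask, n, v in (
            (disc_mask(img, interior), n_interior, v_interior),
            (annulus_mask(img, peripheral), n_peripheral, v_peripheral),
        ):
            idx = np.flatnonzero(mask.ravel())[:n]
            vals.ravel()[idx] = v
        return img, cell

    def test_twofold_interior_gives_plus_one(self):
        img, cell = self._painted_cell(100, 200.0, 100, 100.0)
        res = interior_peripheral_ratio(img, cell, threshold=50.0)
        assert res.log2_ratio == pytest.approx(1.0)

    def test_equal_gives_zero(self):
        img, cell = self._painted_cell(100, 150.0, 100, 150.0)
        res = interior_peripheral_ratio(img, cell, threshold=50.0)
        assert res.log2_ratio == pytest.approx(0.0)

    def test_twofold_peripheral_gives_minus_one(self):
        img, cell = self._painted_cell(100, 100.0, 100, 200.0)
        res = interior_peripheral_ratio(img, cell, threshold=50.0)
        assert res.log2_ratio == pytest.approx(-1.0)

    def test_uses_integrated_intensity_not_mean(self):
        # same pixel value both sides but twice as many interior pixels -> log2 = 1
        img, cell = self._painted_cell(200, 100.0, 100, 100.0)
        res = interior_peripheral_ratio(img, cell, threshold=50.0)
        assert res.log2_ratio == pytest.approx(1.0)
        mean_based = interior_peripheral_ratio(img, cell, threshold=50.0, use_mean=True)
        assert mean_based.log2_ratio == pytest.approx(0.0)

    def test_empty_region_raises(self, constant_image):
        img = PixelImage(values=np.full((201, 201), 10.0), pixel_size_um=0.1)
        cell = DiscROI(center=(100, 100), radius_um=8.0)
        with pytest.raises(ValueError, match="above-threshold"):
            interior_peripheral_ratio(img, cell, threshold=50.0)

    def test_scale_invariance_with_coscaled_threshold(self):
        img, cell = self._painted_cell(130, 180.0, 70, 90.0)
        r1 = interior_peripheral_ratio(img, cell, threshold=50.0)
        img2 = PixelImage(values=img.values * 3.7, pixel_size_um=0.1)
        r2 = interior_peripheral_ratio(img2, cell, threshold=50.0 * 3.7)
        assert r1.log2_ratio == pytest.approx(r2.log2_ratio)


class TestThresholdedPearson:
    def test_identical_channels_give_one(self, make_scene):
        channels, truth = generate_coelomocyte(make_scene(noise_sd=5.0))
        img = channels[0]
        region = disc_mask(img, truth.cell)
        res = thresholded_pearson(img, img, region, 60.0, 60.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_complemented_channel_gives_minus_one(self, make_scene):
        channels, truth = generate_coelomocyte(make_scene(noise_sd=5.0))
        img = channels[0]
        comp = PixelImage(values=500.0 - img.values, pixel_size_um=img.pixel_size_um)
        region = disc_mask(img, truth.cell)
        res = thresholded_pearson(img, comp, region, 60.0, 60.0)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_matches_direct_formula(self, make_scene, make_endosome):
        e = make_endosome(
            ring_intensity=(100.0, 90.0), arc_center_deg=(30.0, 60.0),
            arc_coverage=(0.25, 0.4), arc_intensity=(300.0, 280.0),
        )
        channels, truth = generate_coelomocyte(make_scene(endosomes=(e,), noise_sd=12.0))
        a, b = channels
        region = disc_mask(a, truth.cell)
        t1, t2 = 70.0, 65.0
        res = thresholded_pearson(a, b, region, t1, t2, include="union")

        sel = region & ((a.values > t1) | (b.values > t2))
        x, y = a.values[sel], b.values[sel]
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.pearson_r == pytest.approx(expected, abs=1e-12)
        assert res.n_pixels == sel.sum()

    def test_inclusion_rules_differ(self, make_scene, make_endosome):
        e = make_endosome(
            ring_intensity=(100.0, 90.0), arc_center_deg=(30.0, 210.0),
            arc_coverage=(0.3, 0.3), arc_intensity=(300.0, 280.0),
        )
        channels, truth = generate_coelomocyte(make_scene(endosomes=(e,), noise_sd=3.0))
        region = disc_mask(channels[0], truth.cell)
        r_union = thresholded_pearson(*channels, region, 150.0, 150.0, include="union")
        r_all = thresholded_pearson(*channels, region, 150.0, 150.0, include="all")
        assert r_union.n_pixels < r_all.n_pixels

    def test_zero_variance_raises(self, constant_image):
        img = constant_image(value=50.0)
        with pytest.raises(ValueError, match="variance"):
            thresholded_pearson(img, img, None, 10.0, 10.0, include="all")

    def test_shape_mismatch_raises(self, constant_image):
        with pytest.raises(ValueError, match="shape"):
            thresholded_pearson(constant_image(), constant_image(shape=(32, 32)),
                                None, 0, 0)


class TestMeanIntensityAboveThreshold:
    def test_constant_region(self, constant_image):
        img = constant_image(value=50.0)
        region = np.ones(img.shape, dtype=bool)
        res = mean_intensity_above_threshold(img, region, 10.0)
        assert res.mean == 50.0
        assert res.n_pixels == img.values.size

    def test_all_below_is_flagged_empty(self, constant_image):
        img = constant_image(value=5.0)
        res = mean_intensity_above_threshold(img, np.ones(img.shape, bool), 10.0)
        assert res.empty and res.mean is None and res.n_pixels == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        img = PixelImage(values=rng.uniform(0, 100, (50, 50)), pixel_size_um=0.1)
        region = rng.uniform(size=(50, 50)) > 0.5
        res = mean_intensity_above_threshold(img, region, 40.0)
        sel = img.values[region]
        expected = sel[sel > 40.0]
        assert res.n_pixels == expected.size
        assert res.mean == pytest.approx(expected.mean(), abs=1e-12)


class TestCellArea:
    def test_empty_mask(self):
        assert cell_area(np.zeros((10, 10), bool), 0.1) == 0.0

    def test_hundred_pixels(self):
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        assert cell_area(mask, 0.1) == pytest.approx(1.0)

    def test_disc_area_close_to_analytic(self, constant_image):
        img = PixelImage(values=np.zeros((101, 101)), pixel_size_um=0.1)
        mask = disc_mask(img, DiscROI(center=(50, 50), radius_um=2.5))  # 25 px
        analytic = np.pi * 2.5**2
        assert abs(cell_area(mask, 0.1) - analytic) / analytic < 0.02


class TestFiberLength:
    def test_horizontal_line(self):
        mask = np.zeros((5, 15), bool)
        mask[2, 2:13] = True  # 11 pixels, 10 orthogonal steps
        assert fiber_length(mask, 0.1) == [pytest.approx(1.0)]

    def test_diagonal_line(self):
        mask = np.zeros((15, 15), bool)
        for i in range(11):
            mask[i + 2, i + 2] = True
        (length,) = fiber_length(mask, 0.1)
        assert length == pytest.approx(10 * np.sqrt(2) * 0.1)

    def test_empty_mask(self):
        assert fiber_length(np.zeros((4, 4), bool), 0.1) == []

    def test_two_components_two_lengths(self):
        mask = np.zeros((20, 20), bool)
        mask[2, 2:8] = True
        mask[10, 2:13] = True
        lengths = sorted(fiber_length(mask, 0.1))
        assert lengths == [pytest.approx(0.5), pytest.approx(1.0)]
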