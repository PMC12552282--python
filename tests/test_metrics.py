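"""Per-tissue metrics: STDmin, modal SI, two-tissue split, SNR/CNR, entropy,
edge sharpness, and the assembled ROI assessment."""

import numpy as np
import pytest

from oracles import brute_std_min

from ctiq import (
    NoiseMap,
    PhantomSpec,
    RoiImage,
    assess_roi,
    cnr,
    edge_sharpness,
    generate_phantom,
    grey_entropy,
    highpass_attenuation,
    highpass_residual,
    lowpass,
    modal_si,
    snr,
    split_two_tissues,
    std_filter,
    std_min,
)
from ctiq.calibration import order_statistic_factor
from ctiq.exceptions import (
    BimodalityError,
    EmptyRoiError,
    InsufficientBoundaryError,
    RoiTooSmallError,
    ZeroNoiseError,
)
from ctiq.metrics import EDGE_WIDTH_PER_SIGMA, TwoTissueQuality


def _noise_map(values):
    values = np.asarray(values, dtype=float)
    return NoiseMap(values, 3.0, RoiImage(np.zeros_like(values)))


class TestStdMin:
    def test_constant_map_returns_constant(self):
        nm = _noise_map(np.full((40, 40), 3.5))
        assert std_min(nm) == pytest.approx(3.5, abs=1e-12)

    def test_selects_cold_patch(self):
        field = np.full((64, 64), 5.0)
        field[10:40, 10:40] = 1.0  # cold patch larger than a 12-px circle
        assert std_min(_noise_map(field)) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_candidates_error_names_requirement(self):
        nm = _noise_map(np.full((13, 13), 2.0))  # exactly one candidate circle
        with pytest.raises(RoiTooSmallError, match="diameter 12"):
            std_min(nm, k_lowest=5)

    def test_order_statistic_bound_and_seed_stability(self):
        # mean of the five lowest can never exceed the spatial mean, and the
        # ratio to sigma*a is stable across seeds
        a = highpass_attenuation(2.0)
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = RoiImage(rng.normal(0, 10.0, (128, 128)))
            nm = std_filter(highpass_residual(img, 2.0), 3)
            value = std_min(nm)
            assert value <= np.nanmean(nm.local_std)
            ratios.append(value / (10.0 * a))
        ratios = np.asarray(ratios)
        assert np.all(np.abs(ratios / ratios.mean() - 1.0) < 0.10)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        field = rng.uniform(1.0, 4.0, (24, 24))
        field[:2, :] = np.nan  # undefined strip
        region = np.ones((24, 24), bool)
        region[:, -3:] = False
        ours = std_min(_noise_map(field), region, region_diameter_px=6, k_lowest=4)
        ref = brute_std_min(field, region, 6, 4)
        assert ours == pytest.approx(ref, abs=1e-12)


class TestModalSi:
    def test_constant_image(self):
        assert modal_si(RoiImage(np.full((10, 10), 68.0))) == 68.0

    def test_most_populated_bin_wins(self):
        vals = np.array([0.0] * 10 + [100.0] * 3)
        img = RoiImage(vals.reshape(1, -1))
        assert modal_si(img) == 0.0

    def test_gaussian_sample_recovers_mode(self):
        rng = np.random.default_rng(123)
        vals = rng.normal(77.7, 10.0, 10_000)
        img = RoiImage(vals.reshape(100, 100))
        assert modal_si(img) == pytest.approx(77.7, abs=4.0)

    def test_empty_mask_errors(self):
        img = RoiImage(np.zeros((4, 4)))
        with pytest.raises(EmptyRoiError):
            modal_si(img, np.zeros((4, 4), bool))


class TestSplitTwoTissues:
    def test_noiseless_step_split_exactly(self):
        truth = generate_phantom(PhantomSpec(si_low=50.0, si_high=150.0, shape=(32, 40)))
        mlow, mhigh, thr = split_two_tissues(truth.image)
        assert 50.0 < thr < 150.0
        assert np.array_equal(mlow, truth.tissue_masks[0])
        assert np.array_equal(mhigh, truth.tissue_masks[1])

    def test_noisy_phantom_assigns_99_percent_correctly(self):
        truth = generate_phantom(
            PhantomSpec(si_low=50.0, si_high=150.0, noise_sigma=10.0, seed=4)
        )
        mlow, mhigh, _ = split_two_tissues(truth.image)
        tlow, thigh = truth.tissue_masks
        correct = (mlow & tlow).sum() + (mhigh & thigh).sum()
        assert correct / (tlow.sum() + thigh.sum()) >= 0.99

    def test_constant_image_is_not_bimodal(self):
        with pytest.raises(BimodalityError, match="bimodal"):
            split_two_tissues(RoiImage(np.full((16, 16), 80.0)))

    def test_unimodal_gaussian_is_not_bimodal(self):
        rng = np.random.default_rng(2)
        img = RoiImage(rng.normal(100.0, 15.0, (64, 64)))
        with pytest.raises(BimodalityError):
            split_two_tissues(img)


class TestRatios:
    def test_snr_examples(self):
        assert snr(100.0, 20.0) == 5.0
        assert snr(0.0, 20.0) == 0.0
        assert snr(68.4, 11.6) == pytest.approx(68.4 / 11.6, rel=1e-12)

    def test_snr_zero_noise_is_an_error_not_infinity(self):
        with pytest.raises(ZeroNoiseError, match="zero noise"):
            snr(68.0, 0.0)

    def test_cnr_examples(self):
        assert cnr(50.0, 150.0, 10.0, 10.0) == 10.0
        assert cnr(100.0, 100.0, 5.0, 15.0) == 0.0
        assert cnr(60.0, 140.0, 8.0, 12.0) == 8.0

    def test_cnr_zero_noise_errors(self):
        with pytest.raises(ZeroNoiseError):
            cnr(50.0, 150.0, 0.0, 0.0)


class TestEntropy:
    def test_constant_is_zero_bits(self):
        assert grey_entropy(RoiImage(np.full((8, 8), 3.0))) == 0.0

    def test_two_equal_bins_is_one_bit(self):
        vals = np.array([0.0] * 8 + [30.0] * 8).reshape(4, 4)
        assert grey_entropy(RoiImage(vals)) == pytest.approx(1.0, abs=1e-12)

    def test_half_quarter_eighth_eighth_is_175_bits(self):
        vals = np.array([0.0] * 4 + [25.0] * 2 + [50.0] * 1 + [75.0] * 1)
        assert grey_entropy(RoiImage(vals.reshape(2, 4))) == pytest.approx(1.75, abs=1e-12)


class TestEdgeSharpness:
    def test_ideal_step_is_sampling_limited(self):
        truth = generate_phantom(PhantomSpec(si_low=50.0, si_high=150.0))
        mlow, mhigh, _ = split_two_tissues(truth.image)
        assert edge_sharpness(truth.image, mlow, mhigh) <= 1.2

    @pytest.mark.parametrize("blur", [1.0, 2.0])
    def test_blurred_step_recovers_erf_width(self, blur):
        truth = generate_phantom(
            PhantomSpec(si_low=50.0, si_high=150.0, edge_blur_sigma=blur)
        )
        mlow, mhigh, _ = split_two_tissues(lowpass(truth.image))
        width = edge_sharpness(truth.image, mlow, mhigh)
        assert width == pytest.approx(EDGE_WIDTH_PER_SIGMA * blur, rel=0.10)

    def test_noisy_blurred_step_within_20_percent(self):
        truth = generate_phantom(
            PhantomSpec(si_low=50.0, si_high=150.0, edge_blur_sigma=2.0,
                        noise_sigma=5.0, seed=3)
        )
        mlow, mhigh, _ = split_two_tissues(lowpass(truth.image))
        width = edge_sharpness(truth.image, mlow, mhigh)
        assert width == pytest.approx(EDGE_WIDTH_PER_SIGMA * 2.0, rel=0.20)

    def test_pixel_spacing_scales_width(self):
        truth = generate_phantom(
            PhantomSpec(si_low=50.0, si_high=150.0, edge_blur_sigma=2.0)
        )
        mlow, mhigh, _ = split_two_tissues(truth.image)
        w1 = edge_sharpness(truth.image, mlow, mhigh)
        scaled = RoiImage(truth.image.pixels, pixel_spacing=0.25)
        assert edge_sharpness(scaled, mlow, mhigh) == pytest.approx(0.25 * w1, rel=1e-9)

    def test_short_boundary_errors(self):
        img = RoiImage(np.zeros((16, 16)))
        mlow = np.zeros((16, 16), bool)
        mhigh = np.zeros((16, 16), bool)
        mlow[8, 2] = True
        mhigh[8, 3] = True
        with pytest.raises(InsufficientBoundaryError, match="boundary"):
            edge_sharpness(img, mlow, mhigh)


class TestAssessRoi:
    def test_zero_noise_raises_zero_noise_error(self):
        truth = generate_phantom(PhantomSpec(si_low=68.0, shape=(64, 64)))
        with pytest.raises(ZeroNoiseError, match="zero noise"):
            assess_roi(truth.image)

    def test_one_tissue_recovery(self):
        truth = generate_phantom(
            PhantomSpec(si_low=68.0, noise_sigma=10.0, seed=9)
        )
        res = assess_roi(truth.image)
        assert not isinstance(res, TwoTissueQuality)
        assert res.si == pytest.approx(68.0, abs=4.0)
        a = highpass_attenuation(2.0)
        b = order_statistic_factor(0.0)
        assert res.snr == pytest.approx(68.0 / (10.0 * a * b), rel=0.15)

    def test_two_tissue_recovery(self):
        truth = generate_phantom(
            PhantomSpec(si_low=50.0, si_high=150.0, noise_sigma=10.0, seed=1)
        )
        res = assess_roi(truth.image)
        assert isinstance(res, TwoTissueQuality)
        assert res.delta_si == pytest.approx(res.high.si - res.low.si, abs=1e-12)
        a = highpass_attenuation(2.0)
        b = order_statistic_factor(0.0)
        assert res.cnr == pytest.approx(100.0 / (10.0 * a * b), rel=0.15)

    def test_snr_and_cnr_decrease_with_noise(self, suite_results):
        # stronger noise -> lower SNR and CNR on matched phantoms
        for corr in (0.0, 1.5):
            for blur in (0.0, 1.0, 2.0):
                series = [suite_results[(s, corr, blur)] for s in (5.0, 10.0, 20.0, 40.0)]
                snrs = [r.low.snr for r in series]
                cnrs = [r.cnr for r in series]
                assert all(x > y for x, y in zip(snrs, snrs[1:]))
                assert all(x > y for x, y in zip(cnrs, cnrs[1:]))

    def test_offset_invariance(self):
        # shifting by a multiple of the bin width moves SI exactly and leaves
        # every other metric unchanged
        truth = generate_phantom(
            PhantomSpec(si_low=50.0, si_high=150.0, noise_sigma=10.0,
                        edge_blur_sigma=1.0, seed=6)
        )
        base = assess_roi(truth.image)
        shifted_img = RoiImage(truth.image.pixels + 40.0)
        shifted = assess_roi(shifted_img)
        assert shifted.low.si == pytest.approx(base.low.si + 40.0, abs=1e-9)
        assert shifted.high.si == pytest.approx(base.high.si + 40.0, abs=1e-9)
        assert shifted.delta_si == pytest.approx(base.delta_si, abs=1e-9)
        assert shifted.low.std_min == pytest.approx(base.low.std_min, abs=1e-9)
        assert shifted.high.std_min == pytest.approx(base.high.std_min, abs=1e-9)
        assert shifted.cnr == pytest.approx(base.cnr, rel=1e-9)
        assert shifted.low.entropy_bits == pytest.approx(base.low.entropy_bits, abs=1e-9)
        assert shifted.high.entropy_bits == pytest.approx(base.high.entropy_bits, abs=1e-9)
        assert shifted.sharpness_width == pytest.approx(base.sharpness_width, rel=1e-6)
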