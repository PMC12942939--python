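"""Preprocessing chain: each stage against closed-form oracles and invariants."""

import numpy as np
import pytest

from ramanquant.exceptions import (
    ConfigError,
    DegenerateFitError,
    NormalizationError,
    RangeError,
    ValidationError,
)
from ramanquant.io import SpectralDataset, Spectrum
from ramanquant.preprocess import (
    PreprocessConfig,
    baseline_emsc,
    baseline_polynomial,
    crop,
    despike_median,
    interpolate_to_grid,
    normalize_area,
    run_chain,
    smooth_savitzky_golay,
)
from ramanquant.simulate import SimConfig, generate


def _ds(grid, columns, targets=None):
    return SpectralDataset(wavenumbers=np.asarray(grid, float),
                           intensities=np.column_stack(columns),
                           targets=targets)


class TestCrop:
    def test_closed_interval(self):
        ds = _ds([1, 2, 3, 4, 5], [np.arange(5.0)])
        out = crop(ds, 2, 4)
        assert np.array_equal(out.wavenumbers, [2, 3, 4])

    def test_full_range_is_identity(self, small_ds):
        out = crop(small_ds, small_ds.wavenumbers[0], small_ds.wavenumbers[-1])
        assert out.equals(small_ds)

    def test_empty_result_rejected(self):
        ds = _ds([1, 2, 3, 4, 5], [np.arange(5.0)])
        with pytest.raises(ValidationError):
            crop(ds, 10, 11)

    def test_targets_untouched(self, small_ds):
        out = crop(small_ds, small_ds.wavenumbers[2], small_ds.wavenumbers[-1])
        assert np.array_equal(out.targets, small_ds.targets)


class TestInterpolate:
    def test_same_grid_identity(self, small_ds):
        out = interpolate_to_grid(small_ds, small_ds.wavenumbers)
        assert np.allclose(out.intensities, small_ds.intensities)

    def test_affine_function_exact(self):
        grid = np.linspace(800.0, 810.0, 11)
        ds = _ds(grid, [2 * grid + 1])
        query = np.array([800.5, 803.3, 809.9])
        out = interpolate_to_grid(ds, query)
        assert np.allclose(out.intensities[:, 0], 2 * query + 1, atol=1e-12)

    def test_midpoint(self):
        ds = _ds([800.0, 802.0, 804.0], [np.array([0.0, 4.0, 8.0])])
        out = interpolate_to_grid(ds, np.array([800.0, 801.0, 802.0]))
        assert out.intensities[1, 0] == pytest.approx(2.0)

    def test_extrapolation_rejected(self, small_ds):
        bad = np.linspace(small_ds.wavenumbers[0] - 5, small_ds.wavenumbers[-1], 5)
        with pytest.raises(RangeError):
            interpolate_to_grid(small_ds, bad)


class TestDespike:
    def test_spike_removed(self):
        ds = _ds(range(5), [np.array([1.0, 1.0, 9.0, 1.0, 1.0])])
        out = despike_median(ds, 3)
        assert np.array_equal(out.intensities[:, 0], np.ones(5))

    def test_constant_unchanged(self):
        ds = _ds(range(5), [np.full(5, 3.3)])
        assert np.array_equal(despike_median(ds, 3).intensities, ds.intensities)

    def test_monotone_ramp_interior_unchanged(self):
        ds = _ds(range(4), [np.array([1.0, 2.0, 3.0, 4.0])])
        out = despike_median(ds, 3)
        assert np.array_equal(out.intensities[1:3, 0], [2.0, 3.0])

    def test_even_window_rejected(self, small_ds):
        with pytest.raises(ConfigError):
            despike_median(small_ds, 4)

    def test_shift_equivariance(self, small_ds):
        shifted = small_ds.with_intensities(small_ds.intensities + 7.5)
        a = despike_median(small_ds, 3).intensities + 7.5
        b = despike_median(shifted, 3).intensities
        assert np.allclose(a, b, atol=1e-12)


class TestBaselinePolynomial:
    def test_pure_polynomial_removed(self):
        w = np.linspace(800, 1800, 200)
        y = 3.0 + 0.01 * w + 1e-5 * w ** 2
        out = baseline_polynomial(Spectrum(w, y), degree=2)
        assert np.max(np.abs(out.intensities)) < 1e-8 * np.max(np.abs(y))

    def test_constant_degree_zero(self):
        w = np.linspace(0, 1, 50)
        out = baseline_polynomial(Spectrum(w, np.full(50, 4.2)), degree=0)
        assert np.allclose(out.intensities, 0.0, atol=1e-12)

    def test_peak_height_preserved(self):
        w = np.linspace(800, 1800, 1024)
        bg = 5 + 0.003 * (w - 800) - 1e-6 * (w - 800) ** 2
        peak = 2.0 * np.exp(-0.5 * ((w - 1300) / 10) ** 2)
        out = baseline_polynomial(Spectrum(w, bg + peak), degree=5)
        apex = out.intensities[np.argmin(np.abs(w - 1300))]
        assert apex == pytest.approx(2.0, rel=0.05)


class TestBaselineEMSC:
    def _reference(self):
        w = np.linspace(800, 1800, 300)
        m = np.exp(-0.5 * ((w - 1200) / 30) ** 2) + 0.5 * np.exp(
            -0.5 * ((w - 1600) / 40) ** 2)
        return w, m

    def test_scaled_plus_offset_recovers_reference(self):
        w, m = self._reference()
        ds = _ds(w, [2.0 * m + 3.0])
        out = baseline_emsc(ds, reference=m, emsc_degree=0)
        assert np.allclose(out.intensities[:, 0], m, atol=1e-10)

    def test_identity_member(self):
        w, m = self._reference()
        out = baseline_emsc(_ds(w, [m]), reference=m, emsc_degree=0)
        assert np.allclose(out.intensities[:, 0], m, atol=1e-10)

    def test_linear_term_member(self):
        w, m = self._reference()
        w_norm = 2 * (w - w[0]) / (w[-1] - w[0]) - 1
        x = 1.5 * m + 2.0 + 0.5 * w_norm
        out = baseline_emsc(_ds(w, [x]), reference=m, emsc_degree=1)
        assert np.allclose(out.intensities[:, 0], m, atol=1e-8)

    def test_degenerate_scale_rejected(self):
        w, m = self._reference()
        with pytest.raises(DegenerateFitError):
            baseline_emsc(_ds(w, [-m]), reference=m, emsc_degree=0)

    def test_exact_member_property(self, rng):
        # any x = b*m + poly is corrected back to m (closed-form least squares)
        w, m = self._reference()
        w_norm = 2 * (w - w[0]) / (w[-1] - w[0]) - 1
        for _ in range(5):
            b = rng.uniform(0.5, 3.0)
            p = rng.uniform(-1, 1, size=3)
            x = b * m + p[0] + p[1] * w_norm + p[2] * w_norm ** 2
            out = baseline_emsc(_ds(w, [x]), reference=m, emsc_degree=2)
            rel = np.linalg.norm(out.intensities[:, 0] - m) / np.linalg.norm(m)
            assert rel < 1e-8


class TestSavitzkyGolay:
    def test_polynomial_reproduced(self):
        w = np.linspace(0, 1, 60)
        y = 1 + 2 * w + 3 * w ** 2 - w ** 3
        out = smooth_savitzky_golay(_ds(w, [y]), window=11, order=3)
        assert np.allclose(out.intensities[5:-5, 0], y[5:-5], atol=1e-10)

    def test_noise_variance_decreases(self, rng):
        w = np.linspace(0, 1, 400)
        y = rng.standard_normal(400)
        out = smooth_savitzky_golay(_ds(w, [y]), window=11, order=3)
        assert out.intensities[:, 0].var() < y.var()

    def test_sg31_is_moving_average(self):
        out = smooth_savitzky_golay(_ds([0, 1, 2], [np.array([0.0, 3.0, 0.0])]),
                                    window=3, order=1)
        assert out.intensities[1, 0] == pytest.approx(1.0)

    def test_invalid_params(self, small_ds):
        with pytest.raises(ConfigError):
            smooth_savitzky_golay(small_ds, window=4, order=2)
        with pytest.raises(ConfigError):
            smooth_savitzky_golay(small_ds, window=5, order=5)

    def test_shift_equivariance(self, small_ds):
        shifted = small_ds.with_intensities(small_ds.intensities - 2.5)
        a = smooth_savitzky_golay(small_ds, 5, 2).intensities - 2.5
        b = smooth_savitzky_golay(shifted, 5, 2).intensities
        assert np.allclose(a, b, atol=1e-10)


class TestNormalizeArea:
    def test_arithmetic(self):
        out = normalize_area(_ds(range(3), [np.array([1.0, 1.0, 2.0])]))
        assert np.allclose(out.intensities[:, 0], [0.25, 0.25, 0.5])

    def test_idempotent(self, small_ds):
        once = normalize_area(small_ds)
        twice = normalize_area(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-15)
        assert np.allclose(once.intensities.sum(axis=0), 1.0)

    def test_zero_sum_named(self):
        ds = _ds(range(3), [np.array([1.0, -1.0, 0.0])])
        ds.ids = ["bad-spec"]
        with pytest.raises(NormalizationError, match="bad-spec"):
            normalize_area(ds)


class TestRunChain:
    def test_neutral_config_is_identity(self, small_ds):
        cfg = PreprocessConfig(despike_window=None, baseline_method="none",
                               sg_window=None, normalize=False)
        out, report = run_chain(small_ds, cfg)
        assert out.equals(small_ds)
        assert report.stages == []

    def test_invalid_config_fails_before_compute(self, small_ds):
        cfg = PreprocessConfig(sg_window=8)
        with pytest.raises(ConfigError):
            run_chain(small_ds, cfg)

    def test_stage_order(self, sim_small):
        ds, _ = sim_small
        cfg = PreprocessConfig(crop_lo=900.0, crop_hi=1700.0)
        _, report = run_chain(ds, cfg)
        assert report.stage_names() == [
            "crop", "despike_median", "baseline_polynomial",
            "smooth_savitzky_golay", "normalize_area",
        ]

    def test_recovers_pure_signal_zero_noise(self):
        # spikes + quadratic fluorescence, no noise: the chain (with the
        # baseline degree matched to the generator's quadratic background)
        # must return the normalized pure Raman signal within 5% L2
        cfg = SimConfig(noise_sd=0.0, spike_rate=1.0, seed=5)
        ds, truth = generate(cfg, subset="raw")
        out, _ = run_chain(ds, PreprocessConfig(poly_degree=3))
        sig = truth.signal / truth.signal.sum(axis=0)
        rel = np.linalg.norm(out.intensities - sig, axis=0) / np.linalg.norm(sig, axis=0)
        assert rel.max() < 0.05

    def test_shapes_and_targets_preserved(self, sim_small):
        ds, _ = sim_small
        out, _ = run_chain(ds, PreprocessConfig())
        assert out.intensities.shape == ds.intensities.shape
        assert np.array_equal(out.targets, ds.targets)

    def test_config_round_trip(self):
        cfg = PreprocessConfig(crop_lo=900.0, crop_hi=1700.0, poly_degree=3)
        back = PreprocessConfig.from_dict(cfg.to_dict())
        assert back.to_dict() == cfg.to_dict()
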