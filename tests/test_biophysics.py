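"""Closed-form instrument analyses: isotherms, decays, NOE, anisotropy, DSC."""

import numpy as np
import pytest

from amphihelix.biophysics import (
    IsothermTrace,
    anisotropy,
    compression_modulus,
    fit_exponential_decay,
    het_noe,
    mean_modulus_in_band,
    thermogram_peak,
)
from amphihelix.synth import T1_DELAYS_S, T2_DELAYS_MS, synth_traces


class TestCompressionModulus:
    def test_linear_isotherm_closed_form(self):
        A = np.linspace(100, 40, 61)
        trace = IsothermTrace(A, 50 - 0.5 * A)
        _, cs = compression_modulus(trace)
        assert cs == pytest.approx(0.5 * A)
        assert cs[A == 60.0][0] == pytest.approx(30.0)

    def test_constant_pressure_gives_zero(self):
        A = np.linspace(100, 40, 20)
        _, cs = compression_modulus(IsothermTrace(A, np.full_like(A, 20.0)))
        assert np.allclose(cs, 0.0)

    def test_smooth_synthetic_matches_analytic_derivative(self):
        df, truth = synth_traces("isotherm", seed=0)
        trace = IsothermTrace(df["A"].to_numpy(), df["pi"].to_numpy())
        _, cs = compression_modulus(trace)
        expected = truth["cs_inv"](trace.A)
        rel = np.abs(cs[2:-2] - expected[2:-2]) / expected[2:-2]
        assert rel.max() < 0.02

    def test_area_rescaling_consistency(self):
        # rescaling the area axis leaves Cs-1 = -A dpi/dA unchanged
        A = np.linspace(100, 40, 61)
        pi = 50 - 0.5 * A
        _, cs1 = compression_modulus(IsothermTrace(A, pi))
        _, cs2 = compression_modulus(IsothermTrace(2 * A, pi))
        assert cs2 == pytest.approx(cs1)

    def test_band_mean(self):
        pi = np.array([10.0, 26, 30, 34, 50])
        cs = np.array([1.0, 2, 3, 4, 5])
        assert mean_modulus_in_band(pi, cs) == pytest.approx(3.0)

    def test_non_monotone_without_sort_rejected(self):
        A = np.array([100.0, 90, 95, 80, 70])
        with pytest.raises(ValueError):
            compression_modulus(IsothermTrace(A, A * 0.1), sort=False)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compression_modulus(IsothermTrace([1, 2, 3], [1, 2, 3]))


class TestExponentialDecay:
    def test_noiseless_exact_recovery(self):
        t = np.linspace(0, 1.0, 10)
        fit = fit_exponential_decay(t, 2.0 * np.exp(-3.0 * t))
        assert fit.amplitude == pytest.approx(2.0, abs=1e-8)
        assert fit.rate == pytest.approx(3.0, abs=1e-8)

    def test_constant_series_flagged(self):
        fit = fit_exponential_decay([0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])
        assert fit.rate == pytest.approx(0.0, abs=1e-6)
        assert fit.flagged_non_decaying

    @pytest.mark.parametrize("grid,rate", [
        (T2_DELAYS_MS / 1000.0, 12.0),   # transverse grid, R2-like rate (1/s)
        (T1_DELAYS_S, 1.3),              # recovery grid, R1-like rate (1/s)
    ])
    def test_mean_recovery_on_measurement_grids(self, grid, rate, rng):
        """1% Gaussian noise over 500 replicates biases the fitted rate by
        less than 1% on both relaxation delay grids."""
        rates = []
        for _ in range(500):
            h = np.exp(-rate * grid) + rng.normal(0, 0.01, size=len(grid))
            rates.append(fit_exponential_decay(grid, h).rate)
        assert np.mean(rates) == pytest.approx(rate, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([0, 1], [1.0, 0.5])


class TestHetNoe:
    def test_unit_ratio(self):
        ratio, _ = het_noe([0.5], [0.5])
        assert ratio[0] == 1.0

    def test_hand_value(self):
        ratio, _ = het_noe([0.4], [0.5])
        assert ratio[0] == pytest.approx(0.8)

    def test_vector_broadcast_and_error_propagation(self):
        ratio, sigma = het_noe([1.0, 2.0], [2.0, 4.0], [0.1, 0.1], [0.2, 0.2])
        assert ratio == pytest.approx([0.5, 0.5])
        assert sigma == pytest.approx(
            0.5 * np.sqrt((np.array([0.1, 0.1]) / [1, 2]) ** 2
                          + (np.array([0.2, 0.2]) / [2, 4]) ** 2)
        )

    def test_zero_reference_names_index(self):
        with pytest.raises(ZeroDivisionError, match="index 1"):
            het_noe([1.0, 1.0], [1.0, 0.0])


class TestAnisotropy:
    def test_equal_channels_g_one(self):
        assert anisotropy(1.0, 1.0, g=1.0) == pytest.approx(0.0)

    def test_perpendicular_dark_gives_one(self):
        for g in (0.8, 1.0, 1.171):
            assert anisotropy(2.0, 0.0, g=g) == pytest.approx(1.0)

    def test_default_g_hand_value(self):
        # (1 - 1.171) / (1 + 2*1.171) computed by hand
        assert anisotropy(1.0, 1.0) == pytest.approx(-0.171 / 3.342, abs=1e-6)
        assert anisotropy(1.0, 1.0) == pytest.approx(-0.05117, abs=1e-5)

    def test_bounded_for_g_one(self, rng):
        I_par = rng.uniform(0.01, 10, 200)
        I_perp = rng.uniform(0.01, 10, 200)
        r = anisotropy(I_par, I_perp, g=1.0)
        assert np.all(r >= -0.5 - 1e-12) and np.all(r <= 1.0 + 1e-12)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            anisotropy(-1.0, 1.0)

    def test_round_trip_with_planted_r(self):
        df, truth = synth_traces("anisotropy", {"r": [0.05, 0.2, 0.35]}, seed=0)
        r = anisotropy(df["I_par"].to_numpy(), df["I_perp"].to_numpy(),
                       g=truth["g"])
        assert r == pytest.approx(truth["r"])


class TestThermogram:
    def test_symmetric_peak_centre(self):
        df, _ = synth_traces("thermogram", {"centers": [11.0]}, seed=0)
        peaks = thermogram_peak(df["T"], df["cp"])
        assert peaks.Tm == pytest.approx(11.0, abs=0.051)

    def test_constant_offset_invariance(self):
        df, _ = synth_traces("thermogram", {"centers": [11.0]}, seed=0)
        p1 = thermogram_peak(df["T"], df["cp"])
        p2 = thermogram_peak(df["T"], df["cp"] + 5.0)
        assert p1.Tm == p2.Tm
        assert p1.peak_height == pytest.approx(p2.peak_height)

    def test_two_peak_recovery(self):
        df, truth = synth_traces(
            "thermogram",
            {"centers": [9.0, 13.0], "amplitudes": [1.0, 0.6], "widths": [0.5, 0.5]},
            seed=0,
        )
        peaks = thermogram_peak(df["T"], df["cp"])
        assert peaks.Tm == pytest.approx(9.0, abs=0.06)
        assert peaks.secondary_peaks
        assert peaks.secondary_peaks[0][0] == pytest.approx(13.0, abs=0.06)

    def test_boundary_maximum_flagged(self):
        T = np.linspace(5, 20, 100)
        cp = np.linspace(0, 1, 100)  # monotone: maximum at the boundary
        peaks = thermogram_peak(T, cp)
        assert peaks.boundary_flagged

    def test_non_monotone_temperature_rejected(self):
        with pytest.raises(ValueError):
            thermogram_peak([1.0, 3.0, 2.0] + list(range(4, 25)), np.zeros(24))
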