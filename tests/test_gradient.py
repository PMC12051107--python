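"""Calibration, RI interpolation and baseline correction."""

import math

import numpy as np
import pytest

from conftest import profile_from_arrays
from oracles import ols_normal_equations

from densigrad import (
    DEFAULT_BASELINE_EXCLUSIONS,
    GaussianComponent,
    GradientFraction,
    GradientProfile,
    RICalibration,
    correct_baseline,
    fit_ri_density_calibration,
    interpolate_ri,
    ri_to_density,
)
from densigrad.errors import DegenerateInputError, InsufficientBaselineError


class TestCalibration:
    def test_recovers_published_line_from_noiseless_points(self):
        ri = np.linspace(1.355, 1.385, 38)
        cal = fit_ri_density_calibration(zip(ri, 12.46 * ri - 15.62))
        assert cal.slope == pytest.approx(12.46, abs=1e-9)
        assert cal.intercept == pytest.approx(-15.62, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)
        assert cal.n_points == 38

    def test_identity_line_through_two_points(self):
        cal = fit_ri_density_calibration([(0.0, 0.0), (1.0, 1.0)])
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle_on_noisy_data(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1.36, 1.38, 20)
        y = 12.0 * x - 15.0 + rng.normal(0, 0.01, 20)
        cal = fit_ri_density_calibration(zip(x, y))
        slope, intercept = ols_normal_equations(x, y)
        assert cal.slope == pytest.approx(slope, rel=1e-9)
        assert cal.intercept == pytest.approx(intercept, rel=1e-9)
        # residual orthogonality: OLS residuals sum to zero
        resid = y - (cal.slope * x + cal.intercept)
        assert abs(resid.sum()) < 1e-9 * np.abs(y).max()

    @pytest.mark.parametrize("pairs", [[(1.37, 1.44)], [(1.37, 1.44), (1.37, 1.45)]])
    def test_degenerate_inputs_rejected(self, pairs):
        with pytest.raises(DegenerateInputError):
            fit_ri_density_calibration(pairs)


class TestRiToDensity:
    def test_printed_calibration_at_ri_1_3700(self):
        cal = RICalibration(12.46, -15.62, 38, 0.9945)
        assert ri_to_density(cal, 1.3700) == pytest.approx(1.4502, abs=1e-10)
        assert ri_to_density(cal, 0.0) == pytest.approx(-15.62)

    def test_identity_calibration_and_affine_composition(self):
        ident = RICalibration(1.0, 0.0, 2, 1.0)
        assert ri_to_density(ident, 1.369) == 1.369
        # affine in its argument: f(a·x+b) = slope·a·x + slope·b + intercept
        cal = RICalibration(12.46, -15.62, 2, 1.0)
        a, b, x = 2.0, -1.3, 1.37
        assert ri_to_density(cal, a * x + b) == pytest.approx(cal.slope * a * x + cal.slope * b + cal.intercept)


class TestInterpolateRi:
    @staticmethod
    def _odd_ri_profile(ri_by_index: dict[int, float], n: int) -> GradientProfile:
        return GradientProfile(
            fractions=[
                GradientFraction(index=i, raw_concentration=0.0, refractive_index=ri_by_index.get(i))
                for i in range(1, n + 1)
            ]
        )

    def test_exact_linear_data_fills_even_fractions(self):
        prof = interpolate_ri(self._odd_ri_profile({1: 1.380, 3: 1.376, 5: 1.372}, 5))
        ri = {f.index: f.refractive_index for f in prof.fractions}
        assert ri[2] == pytest.approx(1.378)
        assert ri[4] == pytest.approx(1.374)
        assert prof.ri_fit[0] == pytest.approx(-0.002)
        # measured readings retained alongside the fitted values
        assert prof.fractions[0].measured_refractive_index == pytest.approx(1.380)
        assert prof.fractions[1].measured_refractive_index is None

    def test_assigned_ris_strictly_monotone(self):
        rng = np.random.default_rng(3)
        measured = {i: 1.38 - 0.0003 * i + rng.normal(0, 1e-5) for i in range(1, 60, 2)}
        prof = interpolate_ri(self._odd_ri_profile(measured, 60))
        assert np.all(np.diff(prof.ri) < 0)
        slope, intercept = ols_normal_equations(list(measured), list(measured.values()))
        assert prof.ri_fit == pytest.approx((slope, intercept))

    def test_constant_or_missing_ri_rejected(self):
        with pytest.raises(DegenerateInputError):
            interpolate_ri(self._odd_ri_profile({1: 1.37, 3: 1.37, 5: 1.37}, 5))
        with pytest.raises(DegenerateInputError):
            interpolate_ri(self._odd_ri_profile({1: 1.37}, 5))


class TestBaselineCorrection:
    @staticmethod
    def _tilted_profile(slope=0.5, intercept=2.0):
        # abscissa chosen so the default RI exclusion windows apply
        ri = np.linspace(1.3800, 1.3600, 60)
        signal = GaussianComponent(mean=1.3683, sigma=0.0016, amplitude=10.0)(ri)
        conc = signal + slope * (ri - 1.36) * 100 + intercept
        return profile_from_arrays(ri, conc), ri, signal

    def test_known_tilt_removed_and_refit_is_zero(self):
        prof, ri, signal = self._tilted_profile()
        corrected, fit = correct_baseline(prof)
        assert fit.excluded_windows == tuple((lo, hi) for lo, hi in DEFAULT_BASELINE_EXCLUSIONS)
        baseline_mask = ~((ri > 1.3780) | ((ri >= 1.365) & (ri <= 1.372)))
        # corrected baseline fractions sit at (numerically) zero
        resid = corrected.corrected[baseline_mask]
        tail = signal[baseline_mask].max()  # Gaussian tail bleeding past the windows
        assert np.abs(resid).max() <= tail + 1e-6 * np.abs(prof.raw).max()
        refit_slope, refit_intercept = ols_normal_equations(ri[baseline_mask], corrected.corrected[baseline_mask])
        assert abs(refit_slope) < 1e-6 * np.abs(prof.raw).max()
        assert abs(refit_intercept) < 1e-6 * np.abs(prof.raw).max()

    def test_zero_baseline_leaves_signal_untouched(self):
        ri = np.linspace(1.3800, 1.3600, 60)
        signal = np.where((ri >= 1.365) & (ri <= 1.372), 5.0, 0.0)
        corrected, fit = correct_baseline(profile_from_arrays(ri, signal))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(corrected.corrected, signal, atol=1e-12)

    def test_idempotent(self):
        prof, _, _ = self._tilted_profile()
        once, _ = correct_baseline(prof)
        twice, _ = correct_baseline(once)
        span = np.ptp(prof.raw)
        np.testing.assert_allclose(twice.corrected, once.corrected, atol=1e-9 * span)

    def test_preserves_pairwise_signal_differences(self):
        # subtracting a line changes any two fractions' difference by exactly
        # the baseline-line difference at their RIs
        prof, ri, _ = self._tilted_profile(slope=0.9, intercept=-1.0)
        corrected, fit = correct_baseline(prof)
        raw, corr = prof.raw, corrected.corrected
        i, j = 5, 40
        d_raw = raw[i] - raw[j]
        d_corr = corr[i] - corr[j]
        d_line = fit.predict(prof.ri[i]) - fit.predict(prof.ri[j])
        assert d_raw - d_corr == pytest.approx(d_line, abs=1e-12)

    def test_insufficient_baseline_fractions(self):
        ri = np.linspace(1.3700, 1.3660, 12)  # everything inside an exclusion window
        with pytest.raises(InsufficientBaselineError):
            correct_baseline(profile_from_arrays(ri, np.ones(12)), signal_windows=[(1.30, 1.40)])

    def test_requires_ri_everywhere(self):
        prof = GradientProfile(
            fractions=[GradientFraction(index=1, raw_concentration=1.0, refractive_index=1.37),
                       GradientFraction(index=2, raw_concentration=1.0)]
        )
        with pytest.raises(DegenerateInputError):
            correct_baseline(prof)
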