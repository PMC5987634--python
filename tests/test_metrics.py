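import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aiseap.metrics import (WidthError, detect_initial_positivity,
                            fit_power_law, peak_to_peak, phase_plot,
                            rising_dvdt_maxima, waveform_features,
                            width_at_half_amplitude)


class TestPeakToPeak:
    def test_arithmetic_example(self):
        assert peak_to_peak([-3.0, 1.0, 0.5]) == pytest.approx(4.0)

    def test_constant_trace(self):
        assert peak_to_peak(np.full(10, 2.2)) == 0.0

    def test_sine_amplitude(self):
        t = np.linspace(0, 2 * np.pi, 2001)
        assert peak_to_peak(3.0 * np.sin(t)) == pytest.approx(6.0, rel=1e-5)

    def test_time_reversal_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        assert peak_to_peak(x) == peak_to_peak(x[::-1])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            peak_to_peak([1.0])


class TestWidthAtHalfAmplitude:
    def test_triangle_half_height(self):
        """Symmetric triangle of base width w has half-height width w/2."""
        w = 2.0
        t = np.linspace(-2, 2, 4001)
        trace = np.clip(1 - np.abs(t) / (w / 2), 0, None)
        assert width_at_half_amplitude(trace, t) == pytest.approx(w / 2,
                                                                  abs=2e-3)

    def test_gaussian_fwhm(self):
        sg = 0.3
        t = np.linspace(-3, 3, 6001)
        trace = np.exp(-(t**2) / (2 * sg**2))
        want = 2 * sg * np.sqrt(2 * np.log(2))
        assert width_at_half_amplitude(trace, t) == pytest.approx(want,
                                                                  abs=2e-3)

    def test_negative_dominant_extremum(self):
        sg = 0.25
        t = np.linspace(-3, 3, 6001)
        trace = -np.exp(-(t**2) / (2 * sg**2))
        want = 2 * sg * np.sqrt(2 * np.log(2))
        assert width_at_half_amplitude(trace, t) == pytest.approx(want,
                                                                  abs=2e-3)

    @given(st.floats(min_value=1.1, max_value=5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_time_rescaling_covariance(self, c):
        t = np.linspace(-4, 4, 3001)
        trace = -np.exp(-(t**2) / 0.18) + 0.3 * np.exp(-((t - 1) ** 2) / 0.5)
        w1 = width_at_half_amplitude(trace, t)
        w2 = width_at_half_amplitude(trace, c * t)
        assert w2 == pytest.approx(c * w1, rel=1e-9)

    def test_time_translation_invariance(self):
        t = np.linspace(0, 5, 2001)
        trace = np.exp(-((t - 2.0) ** 2) / 0.1)
        w1 = width_at_half_amplitude(trace, t)
        w2 = width_at_half_amplitude(trace, t + 17.0)
        assert w1 == pytest.approx(w2, rel=1e-12)

    def test_uncrossed_threshold_is_an_error(self):
        t = np.linspace(0, 1, 101)
        with pytest.raises(WidthError):
            width_at_half_amplitude(t.copy(), t)  # monotone ramp
        with pytest.raises(WidthError):
            width_at_half_amplitude(np.zeros(50), t[:50])


class TestInitialPositivity:
    def _biphasic(self, bump):
        t = np.linspace(0, 10, 2001)
        trace = -np.exp(-((t - 5) ** 2) / 0.5)
        trace += bump * np.exp(-((t - 3) ** 2) / 0.3)
        return trace, t

    def test_pure_negative_spike_is_false(self):
        trace, t = self._biphasic(0.0)
        flag, _ = detect_initial_positivity(trace, t)
        assert flag is False

    def test_leading_bump_is_detected(self):
        trace, t = self._biphasic(0.2)  # bump is 0.2/1.2 ≈ 17% of vpp
        flag, amp = detect_initial_positivity(trace, t)
        assert flag is True
        assert amp == pytest.approx(0.2, rel=0.05)

    def test_flat_trace_is_false(self):
        flag, amp = detect_initial_positivity(np.zeros(100))
        assert flag is False and amp == 0.0

    def test_trailing_positivity_does_not_count(self):
        t = np.linspace(0, 10, 2001)
        trace = -np.exp(-((t - 3) ** 2) / 0.5) + 0.4 * np.exp(-((t - 7) ** 2) / 0.5)
        flag, _ = detect_initial_positivity(trace, t)
        assert flag is False


class TestFitPowerLaw:
    def test_exact_inverse_square(self):
        r = np.geomspace(200, 1000, 20)
        fit = fit_power_law(r, 5e4 * r**-2.0)
        assert fit.k == pytest.approx(-2.0, abs=1e-12)
        assert fit.stderr_k == pytest.approx(0.0, abs=1e-10)
        assert fit.n_points == 20

    def test_exact_monopole(self):
        r = np.geomspace(200, 1000, 12)
        fit = fit_power_law(r, 100.0 / r)
        assert fit.k == pytest.approx(-1.0, abs=1e-12)

    def test_noisy_recovery_within_three_stderr(self, rng):
        r = np.geomspace(200, 1000, 20)
        amps = 1e4 * r**-2.0 * np.exp(rng.normal(0, 0.01, r.size))
        fit = fit_power_law(r, amps)
        assert abs(fit.k + 2.0) < 3 * fit.stderr_k

    @pytest.mark.parametrize("k", [-3.0, -2.5, -2.0, -1.5, -1.0])
    def test_planted_exponent_bias_below_hundredth(self, k):
        r = np.geomspace(200, 1000, 10)
        fit = fit_power_law(r, 1e4 * r**k)
        assert abs(fit.k - k) < 0.01

    def test_restricted_fit_range(self):
        r = np.geomspace(50, 1000, 30)
        amps = 1e4 * r**-2.0
        fit = fit_power_law(r, amps, fit_range=(200, 1000))
        assert fit.fit_range == (200.0, 1000.0)
        assert fit.n_points == int(np.sum((r >= 200) & (r <= 1000)))

    def test_invalid_inputs(self):
        r = np.geomspace(200, 1000, 10)
        with pytest.raises(ValueError):
            fit_power_law(r, -1.0 * np.ones(10))
        with pytest.raises(ValueError):
            fit_power_law(r, 1e4 * r**-2.0, fit_range=(900, 1000))  # <3 points
        with pytest.raises(ValueError):
            fit_power_law(r, 1e4 * r**-2.0, fit_range=(1000, 200))


class TestPhasePlot:
    def test_sine_loop_derivative_amplitude(self):
        dt = 0.001
        t = np.arange(0, 2 * np.pi, dt)
        omega = 3.0
        vm, dvdt = phase_plot(np.sin(omega * t), dt)
        assert np.abs(dvdt).max() == pytest.approx(omega, rel=1e-3)

    def test_constant_trace_has_zero_derivative(self):
        _, dvdt = phase_plot(np.full(100, -70.0), 0.01)
        assert np.all(dvdt == 0)

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            phase_plot([1.0, 2.0], 0.1)

    def test_rising_maxima_counts_double_hump(self):
        t = np.arange(0, 10, 0.005)
        vm = 20 * np.exp(-((t - 4) ** 2) / 0.5) + 80 * np.exp(-((t - 6) ** 2) / 0.3)
        assert rising_dvdt_maxima(vm, 0.005) == 2
        single = 80 * np.exp(-((t - 6) ** 2) / 0.3)
        assert rising_dvdt_maxima(single, 0.005) == 1


def test_waveform_features_bundle():
    t = np.linspace(0, 10, 2001)
    trace = -5 * np.exp(-((t - 5) ** 2) / 0.08) + 1.0 * np.exp(-((t - 3.5) ** 2) / 0.2)
    f = waveform_features(trace, t)
    assert f.vpp == pytest.approx(peak_to_peak(trace))
    assert f.has_initial_positivity is True
    assert f.t_trough == pytest.approx(5.0, abs=0.01)
    assert f.width_half == pytest.approx(
        width_at_half_amplitude(trace, t))


def test_metrics_invariant_to_offset_after_baseline():
    """Adding a constant before baseline subtraction changes nothing."""
    t = np.linspace(0, 10, 1001)
    trace = -np.exp(-((t - 6) ** 2) / 0.1)
    shifted = trace + 12.3
    shifted = shifted - shifted[(t >= 3) & (t <= 4)].mean()
    base = trace - trace[(t >= 3) & (t <= 4)].mean()
    assert peak_to_peak(base) == pytest.approx(peak_to_peak(shifted))
    assert width_at_half_amplitude(base, t) == pytest.approx(
        width_at_half_amplitude(shifted, t))
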