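"""Waveform and spatial statistics of extracellular action potentials.

Peak-to-peak amplitude, width at half peak-to-peak amplitude, detection
of the initial positive deflection that signals soma–AIS axial current,
power-law fits of amplitude-versus-distance decay, and phase plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ExponentFit",
    "WaveformFeatures",
    "WidthError",
    "peak_to_peak",
    "width_at_half_amplitude",
    "detect_initial_positivity",
    "fit_power_law",
    "phase_plot",
    "rising_dvdt_maxima",
    "waveform_features",
]


class WidthError(ValueError):
    """The half-amplitude threshold is not crossed on both sides of the peak."""


@dataclass(frozen=True)
class ExponentFit:
    """Power-law exponent from an OLS fit in double-logarithmic scale."""

    k: float
    intercept: float
    fit_range: tuple[float, float]
    n_points: int
    stderr_k: float
    residual_rms: float


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar features of one EAP trace."""

    vpp: float  # μV
    width_half: float  # ms
    has_initial_positivity: bool
    t_trough: float  # ms
    t_peak: float  # ms


def peak_to_peak(trace) -> float:
    """max − min of the trace over the whole analysis window."""
    trace = np.asarray(trace, float)
    if trace.size < 2:
        raise ValueError("peak_to_peak requires at least 2 samples")
    return float(trace.max() - trace.min())


def _cross_time(t0, y0, t1, y1, level) -> float:
    """Linear interpolation of the crossing time of `level` between samples."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def width_at_half_amplitude(trace, time) -> float:
    """Duration (ms) of the dominant deflection at half peak-to-peak amplitude.

    The dominant extremum is the sample of largest absolute value of the
    (baseline-subtracted) trace.  The threshold sits half of the
    peak-to-peak amplitude away from that extremum, toward baseline; the
    width is the interval between the two threshold crossings bracketing
    the extremum, linearly interpolated between samples.
    """
    trace = np.asarray(trace, float)
    time = np.asarray(time, float)
    if trace.size != time.size or trace.size < 3:
        raise ValueError("trace and time must match and hold >= 3 samples")
    vpp = peak_to_peak(trace)
    if vpp == 0.0:
        raise WidthError("flat trace has no measurable width")
    i0 = int(np.argmax(np.abs(trace)))
    ext = trace[i0]
    level = ext - np.sign(ext) * 0.5 * vpp

    def crossed(a, b):
        # does [a, b] straddle the level, moving away from the extremum?
        return (a - level) * (b - level) <= 0

    left = None
    for i in range(i0, 0, -1):
        if crossed(trace[i - 1], trace[i]):
            left = _cross_time(time[i - 1], trace[i - 1], time[i], trace[i], level)
            break
    right = None
    for i in range(i0, trace.size - 1):
        if crossed(trace[i], trace[i + 1]):
            right = _cross_time(time[i], trace[i], time[i + 1], trace[i + 1], level)
            break
    if left is None or right is None:
        side = "left" if left is None else "right"
        raise WidthError(f"half-amplitude threshold never crossed on the {side} side")
    return float(right - left)


def detect_initial_positivity(
    trace, time=None, ap_reference_time: float | None = None,
    fraction: float = 0.05,
) -> tuple[bool, float]:
    """Detect a positive deflection preceding the main negative trough.

    Returns ``(flag, amplitude)``: True iff a positive local maximum
    exceeding ``fraction`` of the peak-to-peak amplitude occurs before
    the global trough (a signature of axial current between AIS and
    soma).  Flat traces return ``(False, 0.0)``.
    """
    trace = np.asarray(trace, float)
    if trace.size < 3:
        return False, 0.0
    vpp = trace.max() - trace.min()
    if vpp == 0.0:
        return False, 0.0
    i_trough = int(np.argmin(trace))
    pre = trace[:i_trough]
    if pre.size < 3:
        return False, 0.0
    interior = pre[1:-1]
    is_max = (interior >= pre[:-2]) & (interior >= pre[2:]) & (interior > 0)
    if not np.any(is_max):
        return False, 0.0
    amp = float(interior[is_max].max())
    return bool(amp > fraction * vpp), amp


def fit_power_law(
    distances, amplitudes, fit_range: tuple[float, float] = (200.0, 1000.0)
) -> ExponentFit:
    """OLS fit of log10(amplitude) on log10(distance) inside ``fit_range``.

    The slope estimates the exponent k of an amplitude ∝ r^k decay.
    """
    r = np.asarray(distances, float)
    a = np.asarray(amplitudes, float)
    if r.shape != a.shape:
        raise ValueError("distances and amplitudes must have the same shape")
    if np.any(r <= 0) or np.any(a <= 0):
        raise ValueError("distances and amplitudes must all be positive")
    lo, hi = fit_range
    if not lo < hi:
        raise ValueError("fit_range must satisfy r_min < r_max")
    mask = (r >= lo) & (r <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 points inside the fit range [{lo}, {hi}] μm, got {mask.sum()}"
        )
    x = np.log10(r[mask])
    y = np.log10(a[mask])
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return ExponentFit(
        k=float(res.slope),
        intercept=float(res.intercept),
        fit_range=(float(lo), float(hi)),
        n_points=int(mask.sum()),
        stderr_k=float(res.stderr),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def phase_plot(vm, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (Vm, dVm/dt) pairs using a central-difference derivative."""
    vm = np.asarray(vm, float)
    if vm.size < 3:
        raise ValueError("phase_plot requires at least 3 samples")
    return vm, np.gradient(vm, dt)


def rising_dvdt_maxima(vm, dt: float, prominence_fraction: float = 0.05) -> int:
    """Count local maxima of dV/dt on the rising phase (up to the AP peak).

    Maxima with prominence below ``prominence_fraction`` of the global
    dV/dt maximum are ignored.  A biphasic rising phase (two maxima) is
    the phase-plot "kink" signature of non-local AP initiation.
    """
    from scipy.signal import find_peaks

    vm, dvdt = phase_plot(vm, dt)
    i_peak = int(np.argmax(vm))
    rising = dvdt[: i_peak + 1]
    if rising.size < 3:
        return 0
    peaks, _ = find_peaks(rising, prominence=prominence_fraction * dvdt.max())
    return int(peaks.size)


def waveform_features(
    trace, time, positivity_fraction: float = 0.05
) -> WaveformFeatures:
    """Bundle vpp, half-width, initial positivity and extremum times."""
    trace = np.asarray(trace, float)
    time = np.asarray(time, float)
    flag, _ = detect_initial_positivity(trace, time, fraction=positivity_fraction)
    return WaveformFeatures(
        vpp=peak_to_peak(trace),
        width_half=width_at_half_amplitude(trace, time),
        has_initial_positivity=flag,
        t_trough=float(time[np.argmin(trace)]),
        t_peak=float(time[np.argmax(trace)]),
    )
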