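"""Synthetic inputs with known ground truth.

These generators make every downstream stage testable without running
the cable solver: analytic current-source configurations whose fields
have closed forms, EAP-like waveforms with known amplitude, width and
initial positivity, and amplitude-versus-distance profiles with a
planted power-law exponent.

Each generator returns its ground truth alongside the data, and all
noise is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .cable import SimResult
from .morphology import ChannelLayout, SegmentGeometry

__all__ = [
    "make_dipole_currents",
    "make_biphasic_waveform",
    "make_powerlaw_profile",
    "BiphasicTruth",
]


def make_dipole_currents(
    I: float,
    d: float,
    waveform=None,
    time=None,
    segment_length: float = 1.0,
) -> SimResult:
    """Two short colinear segments carrying ±I·w(t): an ideal current dipole.

    The source (+I) sits at x = +d/2 and the sink (−I) at x = −d/2, both
    along the x axis, so the dipole moment p = I·d points along +x and
    the far-field matches ``dipole_potential(I, d, r, θ)`` with θ
    measured from +x.  The currents sum to zero at every instant.

    Returns a :class:`~aiseap.cable.SimResult` so the dipole drops into
    :func:`~aiseap.lsa.field_from_simulation` unchanged.
    """
    if d <= 0:
        raise ValueError("dipole separation d must be positive")
    if segment_length > 1.0:
        raise ValueError("fixture segments must be <= 1 μm")
    if time is None:
        time = np.array([0.0])
    time = np.asarray(time, float)
    if waveform is None:
        waveform = np.ones_like(time)
    waveform = np.asarray(waveform, float)
    if waveform.shape != time.shape:
        raise ValueError("waveform and time must have the same shape")

    half = segment_length / 2.0
    # chain order sink → source so segments remain an ordered chain
    sink = SegmentGeometry(
        np.array([-d / 2 - half, 0.0, 0.0]), np.array([-d / 2 + half, 0.0, 0.0]),
        0.5, "soma", 0,
    )
    source = SegmentGeometry(
        np.array([d / 2 - half, 0.0, 0.0]), np.array([d / 2 + half, 0.0, 0.0]),
        0.5, "axon", 1,
    )
    i_mem = np.vstack([-I * waveform, +I * waveform])
    zeros = np.zeros_like(i_mem)
    return SimResult(
        time=time, Vm=zeros, I_membrane=i_mem,
        I_axial=np.zeros((1, time.size)),
        morphology=[sink, source], layout=ChannelLayout(np.zeros(2), np.zeros(2), np.zeros(2)),
        passive=None, stimulus=None, dt=float(time[1] - time[0]) if time.size > 1 else 0.0,
    )


@dataclass(frozen=True)
class BiphasicTruth:
    """Ground truth stored with a synthetic biphasic waveform."""

    vpp: float
    width_half: float
    positivity_fraction: float
    has_initial_positivity: bool


# canonical trough-then-peak shape in dimensionless time u (trough at u=0)
_REBOUND_AMP = 0.35
_REBOUND_POS = 2.5
_REBOUND_WIDTH = 1.5
_BUMP_POS = -2.5
_BUMP_WIDTH = 1.2
_U_SPAN = 8.0


def _shape(u, bump):
    u = np.asarray(u, float)
    return (
        -np.exp(-(u**2) / 2.0)
        + _REBOUND_AMP * np.exp(-((u - _REBOUND_POS) ** 2) / (2 * _REBOUND_WIDTH**2))
        + bump * np.exp(-((u - _BUMP_POS) ** 2) / (2 * _BUMP_WIDTH**2))
    )


def _continuous_truth(bump):
    """vpp and half-width of the continuous shape, independent of sampling.

    The extrema and threshold crossings are located with scalar
    optimisation/root finding on the analytic expression, so the stored
    truth does not depend on the discrete metric implementation.
    """
    lo = minimize_scalar(lambda u: _shape(u, bump), bounds=(-1.5, 1.5), method="bounded")
    hi = minimize_scalar(lambda u: -_shape(u, bump),
                         bounds=(_REBOUND_POS - 3, _REBOUND_POS + 3), method="bounded")
    v_min = float(lo.fun)
    v_max = float(-hi.fun)
    vpp = v_max - v_min
    u_min = float(lo.x)
    level = v_min + 0.5 * vpp
    left = brentq(lambda u: _shape(u, bump) - level, -_U_SPAN, u_min)
    right = brentq(lambda u: _shape(u, bump) - level, u_min, float(hi.x))
    return vpp, right - left


def make_biphasic_waveform(
    vpp: float = 100.0,
    width: float = 0.5,
    positivity_fraction: float = 0.0,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, BiphasicTruth]:
    """EAP-like trough-then-peak trace with known vpp, width and positivity.

    A difference-of-Gaussians waveform is rescaled in time and amplitude
    so that the continuous-function peak-to-peak equals ``vpp`` (μV) and
    the width at half peak-to-peak equals ``width`` (ms).  An optional
    leading positive bump of ``positivity_fraction × vpp`` precedes the
    trough.

    Returns ``(time, trace, truth)``.
    """
    if vpp <= 0 or width <= 0:
        raise ValueError("vpp and width must be positive")
    if dt >= width:
        raise ValueError("dt must resolve the waveform: dt < width required")

    # iterate once on the bump amplitude: the bump tail shifts vpp slightly
    bump = 0.0
    for _ in range(3 if positivity_fraction > 0 else 1):
        vpp_u, _ = _continuous_truth(bump)
        bump = positivity_fraction * vpp_u
    vpp_u, width_u = _continuous_truth(bump)

    t_scale = width / width_u
    a_scale = vpp / vpp_u
    t_span = _U_SPAN * t_scale
    time = np.arange(0.0, 2 * t_span + dt / 2, dt)
    u = (time - t_span) / t_scale
    trace = a_scale * _shape(u, bump)
    truth = BiphasicTruth(
        vpp=vpp, width_half=width,
        positivity_fraction=positivity_fraction,
        has_initial_positivity=positivity_fraction > 0,
    )
    return time, trace, truth


def make_powerlaw_profile(
    k: float,
    n_points: int = 20,
    noise_sd: float = 0.0,
    seed: int | None = None,
    r_range: tuple[float, float] = (200.0, 1000.0),
    amplitude_at_rmin: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-spaced distances with amplitudes c·r^k and lognormal noise.

    ``noise_sd`` is the standard deviation of the multiplicative
    log-amplitude noise; a seed is mandatory whenever it is nonzero.
    Returns ``(distances, amplitudes, true_k)``.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sd > 0")
    r = np.geomspace(*r_range, n_points)
    c = amplitude_at_rmin / r_range[0] ** k
    amps = c * r**k
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        amps = amps * np.exp(rng.normal(0.0, noise_sd, n_points))
    return r, amps, float(k)
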