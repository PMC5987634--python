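"""Implicit cable-equation solver for unbranched compartment chains.

Each segment obeys

    C_i dV_i/dt = −I_ion,i + Σ_j g_c(i,j) (V_j − V_i) + I_inj,i

with axial coupling conductances computed from the axial resistivity and
the two half-segments in series.  Voltages are advanced with a
Crank–Nicolson step on the tridiagonal system (unconditionally stable);
gating variables are advanced with exact exponential updates using the
rates at the current voltage (staggered update).

Internal unit system: μm, ms, mV, nA, μS, nF, MΩ — a consistent set in
which V = I·R and C dV/dt have no conversion factors.

The per-segment net transmembrane current ``I_membrane`` reported in
:class:`SimResult` is the axial influx Σ_j g_c (V_j − V_i), i.e. the
capacitive + ionic − injected current (outward positive).  Assigning the
injected current's return to its target segment this way makes the source
configuration monopole-free: Σ_i I_membrane,i = 0 to machine precision,
as required for a consistent extracellular forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from . import channels
from .morphology import ChannelLayout, SegmentGeometry, soma_axon_boundary

__all__ = [
    "PassiveParams",
    "StimulusSpec",
    "SimResult",
    "SimulationError",
    "NoActionPotentialError",
    "simulate",
    "axial_current_trace",
]

MAX_DT = 0.025  # ms; larger steps distort the AP upstroke

#: unit conversions into the internal system
_CM_TO_NF_PER_UM2 = 1e-5  # μF/cm² → nF/μm²
_RA_TO_MOHM_UM = 1e-2  # Ω·cm → MΩ·μm
_PS_TO_US = 1e-6  # pS → μS


class SimulationError(RuntimeError):
    """Raised when the integration produces a non-finite state."""


class NoActionPotentialError(RuntimeError):
    """Raised when an operation requires a somatic AP that never occurred."""


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane and cytoplasm parameters."""

    Ra: float = 150.0  # axial resistivity, Ω·cm
    Cm: float = 1.0  # specific capacitance, μF/cm²
    temperature: float = 23.0  # °C, informational only

    def __post_init__(self):
        if self.Ra <= 0 or self.Cm <= 0:
            raise ValueError("Ra and Cm must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """Somatic current step used to trigger a single action potential."""

    target_segment: int = -1  # -1 → soma segment adjacent to the axon
    amplitude: float = 0.08  # nA
    onset: float = 2.0  # ms
    duration: float = 13.0  # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class SimResult:
    """Membrane potentials and currents from one cable simulation.

    Attributes
    ----------
    time : (nt,) ms
    Vm : (n_seg, nt) mV
    I_membrane : (n_seg, nt) nA, net transmembrane current, outward
        positive; sums to zero over segments at every time step.
    I_axial : (n_seg-1, nt) nA at each inter-segment boundary b, positive
        when current flows from segment b+1 into segment b (i.e. from the
        axon toward the soma at the soma–axon junction).
    """

    time: np.ndarray
    Vm: np.ndarray
    I_membrane: np.ndarray
    I_axial: np.ndarray
    morphology: list[SegmentGeometry]
    layout: ChannelLayout
    passive: PassiveParams
    stimulus: StimulusSpec | None
    dt: float

    def section_indices(self, section: str) -> np.ndarray:
        return np.array(
            [s.index for s in self.morphology if s.section_label == section], int
        )

    @property
    def soma_vm(self) -> np.ndarray:
        """Somatic membrane potential (soma segment adjacent to the axon)."""
        return self.Vm[soma_axon_boundary(self.morphology)]

    @property
    def ais_vm(self) -> np.ndarray:
        """Membrane potential at the distal end of the AIS."""
        ais = self.section_indices("ais")
        if ais.size == 0:
            raise ValueError("morphology has no AIS segments")
        return self.Vm[ais.max()]

    def ap_peak_time(self, where: str = "soma") -> float:
        """Time of the AP peak; requires Vm to cross 0 mV at that site."""
        v = self.soma_vm if where == "soma" else self.ais_vm
        if v.max() <= 0.0:
            raise NoActionPotentialError(
                f"no action potential at the {where}: Vm never crosses 0 mV "
                f"(max {v.max():.1f} mV)"
            )
        return float(self.time[np.argmax(v)])


def _coupling_conductances(morph: list[SegmentGeometry], passive: PassiveParams):
    """Axial conductance (μS) between consecutive segment centres."""
    ra = passive.Ra * _RA_TO_MOHM_UM  # MΩ·μm
    half = np.array(
        [ra * (s.length / 2.0) / (np.pi * (s.diameter / 2.0) ** 2) for s in morph]
    )  # MΩ
    return 1.0 / (half[:-1] + half[1:])


def _validate_chain(morph: list[SegmentGeometry]):
    for i, s in enumerate(morph):
        if s.index != i:
            raise ValueError("morphology segments must be indexed in chain order")
    for a, b in zip(morph[:-1], morph[1:]):
        if not np.allclose(a.end_point, b.start_point, atol=1e-6):
            raise ValueError(
                f"segments {a.index} and {b.index} do not share an endpoint; "
                "the solver supports unbranched chains only"
            )


def simulate(
    morphology: list[SegmentGeometry],
    layout: ChannelLayout,
    passive: PassiveParams | None = None,
    stim: StimulusSpec | None = None,
    dt: float = 0.005,
    t_stop: float = 20.0,
    v_init: float | None = None,
    rate_table=None,
) -> SimResult:
    """Integrate the cable equation and return potentials and currents.

    ``stim=None`` runs without injected current.  ``rate_table`` replaces
    the built-in gating kinetics (see :func:`aiseap.channels.load_rate_table`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > MAX_DT:
        raise ValueError(f"dt = {dt} ms rejected; must be <= {MAX_DT} ms")
    if stim is not None and t_stop <= stim.onset:
        raise ValueError("t_stop must exceed the stimulus onset")
    _validate_chain(morphology)
    n = len(morphology)
    if layout.n_segments != n:
        raise ValueError("channel layout does not match the morphology")
    passive = passive or PassiveParams()

    areas = np.array([s.area for s in morphology])  # μm²
    cap = passive.Cm * _CM_TO_NF_PER_UM2 * areas  # nF
    g_c = _coupling_conductances(morphology, passive)  # μS
    gna_max = layout.gNa_bar * _PS_TO_US * areas  # μS
    gk_max = layout.gK_bar * _PS_TO_US * areas
    gl = layout.g_leak * _PS_TO_US * areas

    stim_idx = None
    stim_amp = 0.0
    if stim is not None:
        stim_idx = stim.target_segment
        if stim_idx == -1:
            stim_idx = soma_axon_boundary(morphology)
        if not 0 <= stim_idx < n:
            raise ValueError("stimulus target segment out of range")
        stim_amp = stim.amplitude

    nt = int(round(t_stop / dt)) + 1
    time = np.arange(nt) * dt
    v = np.full(n, layout.E_leak if v_init is None else v_init, float)
    ss = channels.steady_state(v, rate_table)
    m, h, ngate = ss["m"].copy(), ss["h"].copy(), ss["n"].copy()

    vm_out = np.empty((n, nt))
    vm_out[:, 0] = v

    # fixed parts of the tridiagonal system
    g_conn_sum = np.zeros(n)
    np.add.at(g_conn_sum, np.arange(n - 1), g_c)
    np.add.at(g_conn_sum, np.arange(1, n), g_c)
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * g_c  # superdiagonal
    ab[2, :-1] = -0.5 * g_c  # subdiagonal
    c_dt = cap / dt

    for k in range(1, nt):
        # exact exponential gating update with rates frozen at V^n
        for gname, state in (("m", m), ("h", h), ("n", ngate)):
            a = channels.rate(gname, "alpha", v, rate_table)
            b = channels.rate(gname, "beta", v, rate_table)
            tau = 1.0 / (a + b)
            xinf = a * tau
            state += (xinf - state) * (-np.expm1(-dt / tau))

        gna = gna_max * m**3 * h
        gk = gk_max * ngate**4
        g_ion = gna + gk + gl
        e_ion = gna * layout.E_Na + gk * layout.E_K + gl * layout.E_leak  # nA

        i_inj = np.zeros(n)
        if stim is not None:
            t_mid = time[k - 1] + 0.5 * dt
            if stim.onset <= t_mid < stim.onset + stim.duration:
                i_inj[stim_idx] = stim_amp

        diag = c_dt + 0.5 * (g_ion + g_conn_sum)
        rhs = (c_dt - 0.5 * (g_ion + g_conn_sum)) * v + e_ion + i_inj
        rhs[:-1] += 0.5 * g_c * v[1:]
        rhs[1:] += 0.5 * g_c * v[:-1]
        ab[1] = diag
        v = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(v)):
            raise SimulationError(
                f"non-finite membrane potential at step {k} (t = {k * dt:.4f} ms)"
            )
        vm_out[:, k] = v

    i_axial = g_c[:, None] * (vm_out[1:] - vm_out[:-1])  # nA, toward lower index
    i_membrane = np.vstack([i_axial[:1], np.diff(i_axial, axis=0), -i_axial[-1:]])

    return SimResult(
        time=time, Vm=vm_out, I_membrane=i_membrane, I_axial=i_axial,
        morphology=morphology, layout=layout, passive=passive, stimulus=stim,
        dt=dt,
    )


def axial_current_trace(
    result: SimResult,
    boundary: int | None = None,
    align_peak_at: float | None = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial current at an inter-segment boundary, aligned to the somatic AP.

    Parameters
    ----------
    boundary : int, optional
        Boundary index; defaults to the soma–axon junction.
    align_peak_at : float or None
        Shift the time axis so the somatic AP peak sits at this time (ms);
        ``None`` returns the unshifted time axis.

    Returns
    -------
    (time, current) with current positive for axon → soma flow.
    """
    if boundary is None:
        boundary = soma_axon_boundary(result.morphology)
    if not 0 <= boundary < result.I_axial.shape[0]:
        raise ValueError("boundary index out of range")
    trace = result.I_axial[boundary]
    t = result.time
    if align_peak_at is not None:
        t = t - result.ap_peak_time("soma") + align_peak_at
    return t, trace
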