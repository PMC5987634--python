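"""Extracellular potentials by the line-source approximation (LSA).

Each cylindrical segment is treated as a line of uniformly distributed
transmembrane current along its axis; the potential at an electrode is
the analytic line integral of the point-source kernel in an infinite,
homogeneous, isotropic, purely resistive medium (quasi-static):

    V(x) = I / (4πσL) ∫₀^L ds / |x − p(s)|

evaluated in the numerically stable arcsinh closed form.  Potentials are
returned in μV for currents in nA, distances in μm and conductivity in
S/m.  The default conductivity is 0.3 S/m.

The soma cylinder is represented by its axis line segments — no
disk-source correction — matching common practice for this forward
model.  Electrodes that fall on a source segment raise
:class:`SingularElectrodeError` rather than being silently clamped,
because clamped singularities corrupt downstream power-law fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .morphology import SegmentGeometry

__all__ = [
    "SIGMA_DEFAULT",
    "Electrode",
    "FieldRecording",
    "SingularElectrodeError",
    "line_source_potential",
    "point_source_potential",
    "dipole_potential",
    "field_from_simulation",
    "subtract_baseline",
    "electrode_line",
    "electrode_grid",
]

SIGMA_DEFAULT = 0.3  # S/m, extracellular conductivity

#: nA / (S/m · μm) → μV
_UNIT = 1e3


class SingularElectrodeError(ValueError):
    """Electrode lies on a source segment where the LSA kernel is singular."""


@dataclass(frozen=True)
class Electrode:
    """A point electrode at a 3-D position (μm)."""

    position: np.ndarray
    label: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("electrode position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class FieldRecording:
    """Extracellular potential traces on a set of electrodes.

    ``V_ext`` has shape (n_electrodes, n_times) in μV.
    """

    electrodes: list[Electrode]
    time: np.ndarray
    V_ext: np.ndarray
    sigma: float = SIGMA_DEFAULT

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.V_ext = np.asarray(self.V_ext, float)
        if self.sigma <= 0:
            raise ValueError("conductivity must be positive")
        if self.V_ext.shape != (len(self.electrodes), self.time.size):
            raise ValueError("V_ext shape must be (n_electrodes, n_times)")
        if not np.all(np.isfinite(self.V_ext)):
            raise ValueError("V_ext contains non-finite values")

    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.electrodes])

    def to_text(self, path: str | Path, delimiter: str = "\t"):
        """Write one column per electrode; header carries the positions."""
        header = delimiter.join(
            ["time_ms"]
            + [
                f"{e.label or f'e{i}'}@{e.position[0]:g},{e.position[1]:g},{e.position[2]:g}"
                for i, e in enumerate(self.electrodes)
            ]
        )
        data = np.column_stack([self.time, self.V_ext.T])
        np.savetxt(path, data, delimiter=delimiter, header=header, comments="",
                   fmt="%.17g")

    def to_npz(self, path: str | Path):
        """Binary array container (positions, time, potentials, σ)."""
        np.savez(path, positions=self.positions(), time=self.time,
                 V_ext=self.V_ext, sigma=self.sigma,
                 labels=np.array([e.label for e in self.electrodes]))


def _line_kernel(
    starts: np.ndarray, ends: np.ndarray, positions: np.ndarray, sigma: float
) -> np.ndarray:
    """LSA kernel matrix K (μV per nA), shape (n_electrodes, n_segments).

    Handles electrodes on the extended source axis but beyond the segment
    ends (finite limit); raises for electrodes on a segment itself.
    """
    starts = np.atleast_2d(starts)
    ends = np.atleast_2d(ends)
    positions = np.atleast_2d(positions)
    d = ends - starts
    L = np.linalg.norm(d, axis=1)
    u = d / L[:, None]
    w = positions[:, None, :] - starts[None, :, :]  # (m, n, 3)
    hproj = np.einsum("mnk,nk->mn", w, u)
    r2 = np.einsum("mnk,mnk->mn", w, w) - hproj**2
    r = np.sqrt(np.clip(r2, 0.0, None))

    tol = 1e-9 * np.maximum(L, 1.0)
    on_line = r < tol
    on_segment = on_line & (hproj > -tol) & (hproj < L + tol)
    if np.any(on_segment):
        m_idx, n_idx = np.argwhere(on_segment)[0]
        raise SingularElectrodeError(
            f"electrode {m_idx} lies on source segment {n_idx}; the line-source "
            "kernel is singular there"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.arcsinh(hproj / r) - np.arcsinh((hproj - L) / r)
        # on the axis beyond the segment ends the integral has a log form
        val_line = np.abs(np.log(np.abs(hproj) / np.abs(hproj - L)))
    val = np.where(on_line, val_line, val)
    return _UNIT / (4.0 * np.pi * sigma) * val / L


def _as_endpoints(source) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(source, SegmentGeometry):
        return source.start_point, source.end_point
    a, b = source
    return np.asarray(a, float), np.asarray(b, float)


def line_source_potential(source, I, electrode, sigma: float = SIGMA_DEFAULT):
    """Potential (μV) of one uniform line source at one electrode.

    ``source`` is a :class:`SegmentGeometry` or an ``(start, end)`` pair
    of 3-D points; ``I`` (nA) may be a scalar or a time series.
    """
    a, b = _as_endpoints(source)
    pos = electrode.position if isinstance(electrode, Electrode) else np.asarray(electrode, float)
    k = _line_kernel(a[None], b[None], pos[None], sigma)[0, 0]
    return k * np.asarray(I)


def point_source_potential(I, r, sigma: float = SIGMA_DEFAULT):
    """Monopole potential I/(4πσr) in μV (I in nA, r in μm)."""
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    return _UNIT * np.asarray(I) / (4.0 * np.pi * sigma * r)


def dipole_potential(I, d, r, theta, sigma: float = SIGMA_DEFAULT):
    """Far-field current-dipole potential V = I·d·cosθ / (4πσ r²) in μV.

    ``I`` is the dipole current (nA), ``d`` the sink–source separation
    (μm), ``r`` the distance from the dipole centre (μm) and ``theta``
    the angle from the dipole axis.  Valid only for r ≫ d.
    """
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    return _UNIT * np.asarray(I) * d * np.cos(theta) / (4.0 * np.pi * sigma * r**2)


def field_from_simulation(
    result,
    electrodes: list[Electrode],
    sigma: float = SIGMA_DEFAULT,
    morphology: list[SegmentGeometry] | None = None,
) -> FieldRecording:
    """Superpose the LSA potentials of every segment's membrane current.

    ``result`` must provide ``I_membrane`` (n_seg, nt) and ``time``;
    ``morphology`` defaults to ``result.morphology``.
    """
    morph = morphology if morphology is not None else result.morphology
    if len(morph) != result.I_membrane.shape[0]:
        raise ValueError(
            f"morphology has {len(morph)} segments but the simulation carries "
            f"{result.I_membrane.shape[0]} current traces"
        )
    starts = np.array([s.start_point for s in morph])
    ends = np.array([s.end_point for s in morph])
    positions = np.array([e.position for e in electrodes])
    try:
        kernel = _line_kernel(starts, ends, positions, sigma)
    except SingularElectrodeError as err:
        raise SingularElectrodeError(f"{err} (check the electrode layout)") from None
    v_ext = kernel @ result.I_membrane
    return FieldRecording(list(electrodes), result.time, v_ext, sigma)


def subtract_baseline(recording: FieldRecording, ap_peak_time: float) -> FieldRecording:
    """Remove, per electrode, the mean potential in [peak−2, peak−1] ms.

    Idempotent up to floating tolerance.  Raises if the window is not
    fully inside the recorded range.
    """
    t = recording.time
    lo, hi = ap_peak_time - 2.0, ap_peak_time - 1.0
    eps = 1e-9
    if lo < t[0] - eps or hi > t[-1] + eps:
        raise ValueError(
            f"baseline window [{lo:.3f}, {hi:.3f}] ms outside recorded range "
            f"[{t[0]:.3f}, {t[-1]:.3f}] ms"
        )
    mask = (t >= lo - eps) & (t <= hi + eps)
    baseline = recording.V_ext[:, mask].mean(axis=1, keepdims=True)
    return replace(recording, V_ext=recording.V_ext - baseline)


def electrode_line(
    direction,
    r_start: float,
    r_stop: float,
    n: int,
    spacing: str = "log",
    origin=(0.0, 0.0, 0.0),
    label: str = "",
) -> list[Electrode]:
    """Electrodes along a line from ``origin``, at radial offsets r.

    ``direction`` is a 3-vector (normalised internally) or one of
    'x', '-x', 'y', '-y', 'z', '-z'; spacing is 'log' or 'linear'.
    """
    axes = {"x": (1, 0, 0), "-x": (-1, 0, 0), "y": (0, 1, 0), "-y": (0, -1, 0),
            "z": (0, 0, 1), "-z": (0, 0, -1)}
    if isinstance(direction, str):
        direction = axes[direction]
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    if spacing == "log":
        if r_start <= 0:
            raise ValueError("log spacing requires r_start > 0")
        rs = np.geomspace(r_start, r_stop, n)
    elif spacing == "linear":
        rs = np.linspace(r_start, r_stop, n)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    origin = np.asarray(origin, float)
    return [
        Electrode(origin + r * u, f"{label}{i}" if label else f"r{r:g}")
        for i, r in enumerate(rs)
    ]


def electrode_grid(xlim, ylim, nx: int, ny: int, z: float = 0.0) -> list[Electrode]:
    """Planar electrode grid in the z = const plane (for potential maps)."""
    xs = np.linspace(*xlim, nx)
    ys = np.linspace(*ylim, ny)
    return [
        Electrode(np.array([x, y, z]), f"g{i}_{j}")
        for j, y in enumerate(ys)
        for i, x in enumerate(xs)
    ]
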