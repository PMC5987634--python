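"""Simplified soma–axon morphologies as chains of cylindrical segments.

The canonical model is a cylindrical soma (20 μm diameter × 30 μm length,
6 segments) joined to a thin axon (1 μm diameter × 50 μm length, 10
segments).  A 5-μm stretch of the axon is labelled as the axon initial
segment (AIS) and carries all active channels in the axonal-initiation
configuration.  An optional passive dendrite (2 μm × 400 μm) can be
attached on the side of the soma opposite the axon.

Coordinate convention: the model axis is x, the soma is centred at the
origin, the axon extends in −x and the dendrite in +x.  All positions are
in μm.  Segments are ordered along the chain (dendrite distal → soma →
axon distal) so that every segment is coupled only to its index
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SegmentGeometry",
    "ChannelLayout",
    "build_soma_axon",
    "read_swc",
    "segment_indices",
    "soma_axon_boundary",
    "ais_proximal_boundary",
    "point_segment_distance",
    "SOMA_DIAMETER",
    "SOMA_LENGTH",
    "N_SOMA_SEGMENTS",
    "AXON_DIAMETER",
    "AXON_LENGTH",
    "DENDRITE_DIAMETER",
    "DENDRITE_LENGTH",
]

SECTIONS = ("soma", "axon", "ais", "dendrite")

SOMA_DIAMETER = 20.0  # μm
SOMA_LENGTH = 30.0  # μm
N_SOMA_SEGMENTS = 6
AXON_DIAMETER = 1.0  # μm
AXON_LENGTH = 50.0  # μm
AXON_PIECE = 5.0  # nominal axon segment length, μm
DENDRITE_DIAMETER = 2.0  # μm
DENDRITE_LENGTH = 400.0  # μm
N_DENDRITE_SEGMENTS = 10

#: default maximal conductance densities, pS/μm².  The AIS sodium density
#: corresponds to ~1.5 μS over the 5-μm AIS: an effective lumped value
#: strong enough that the spiking AIS acts as a near-voltage-source
#: driving the soma through the axial resistance (the
#: critical-resistive-coupling regime of axonal spike initiation), and
#: sustains the somatic AP across all soma–AIS distances.
DEFAULT_AIS_GNA = 96000.0
DEFAULT_AIS_GK = 3000.0
#: somatic-initiation analog densities (soma carries all active channels)
DEFAULT_SOMA_GNA = 500.0
DEFAULT_SOMA_GK = 100.0
DEFAULT_G_LEAK = 0.3  # pS/μm²
DEFAULT_E_NA = 50.0  # mV
DEFAULT_E_K = -90.0  # mV
DEFAULT_E_LEAK = -70.0  # mV


@dataclass(frozen=True)
class SegmentGeometry:
    """One cylindrical segment of a neurite chain."""

    start_point: np.ndarray  # (3,) μm
    end_point: np.ndarray  # (3,) μm
    diameter: float  # μm
    section_label: str  # one of SECTIONS
    index: int  # order along the chain

    def __post_init__(self):
        object.__setattr__(self, "start_point", np.asarray(self.start_point, float))
        object.__setattr__(self, "end_point", np.asarray(self.end_point, float))
        if self.section_label not in SECTIONS:
            raise ValueError(f"unknown section label {self.section_label!r}")
        if not self.length > 0:
            raise ValueError("segment length must be > 0")
        if not self.diameter > 0:
            raise ValueError("segment diameter must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end_point - self.start_point))

    @property
    def area(self) -> float:
        """Lateral (membrane) area of the cylinder, μm²."""
        return float(np.pi * self.diameter * self.length)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.start_point + self.end_point)


@dataclass
class ChannelLayout:
    """Per-segment maximal conductance densities (pS/μm²) and reversals (mV)."""

    gNa_bar: np.ndarray
    gK_bar: np.ndarray
    g_leak: np.ndarray
    E_Na: float = DEFAULT_E_NA
    E_K: float = DEFAULT_E_K
    E_leak: float = DEFAULT_E_LEAK

    def __post_init__(self):
        self.gNa_bar = np.asarray(self.gNa_bar, float)
        self.gK_bar = np.asarray(self.gK_bar, float)
        self.g_leak = np.asarray(self.g_leak, float)
        for name in ("gNa_bar", "gK_bar", "g_leak"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_segments(self) -> int:
        return self.gNa_bar.size

    def copy(self) -> "ChannelLayout":
        return ChannelLayout(
            self.gNa_bar.copy(), self.gK_bar.copy(), self.g_leak.copy(),
            self.E_Na, self.E_K, self.E_leak,
        )


def _axon_breakpoints(ais_start: float, ais_length: float) -> np.ndarray:
    """Axon node positions (distance from the soma surface) with the AIS
    edges guaranteed to coincide with segment nodes."""
    ais_end = ais_start + ais_length
    axon_length = max(AXON_LENGTH, ais_end)
    pts = set(np.arange(0.0, axon_length + 1e-9, AXON_PIECE))
    pts.add(axon_length)
    pts.add(ais_start)
    pts.add(ais_end)
    bp = np.array(sorted(pts))
    # drop slivers created by AIS edges falling within round-off of a node
    keep = np.concatenate([[True], np.diff(bp) > 1e-9])
    return bp[keep]


def build_soma_axon(
    ais_start: float = 45.0,
    ais_length: float = 5.0,
    include_dendrite: bool = False,
    channel_config: str = "ais_initiation",
    *,
    gNa: float | None = None,
    gK: float | None = None,
    g_leak: float = DEFAULT_G_LEAK,
    E_Na: float = DEFAULT_E_NA,
    E_K: float = DEFAULT_E_K,
    E_leak: float = DEFAULT_E_LEAK,
) -> tuple[list[SegmentGeometry], ChannelLayout]:
    """Build the simplified soma–axon model and its channel layout.

    Parameters
    ----------
    ais_start : float
        Distance (μm) from the somatic end of the axon to the proximal
        edge of the AIS.
    ais_length : float
        AIS length in μm (default 5).
    include_dendrite : bool
        Attach a passive dendrite (2 × 400 μm) opposite the axon.
    channel_config : str
        ``"ais_initiation"`` places Na/K channels on AIS segments only;
        ``"somatic_initiation"`` places them on soma segments only.
    gNa, gK : float, optional
        Override the active-channel densities (pS/μm²).  Defaults depend
        on the configuration: 96000/3000 on the AIS, 500/100 on the soma.

    Returns
    -------
    (morphology, layout)
        Ordered chain of :class:`SegmentGeometry` and the matching
        :class:`ChannelLayout`.
    """
    if ais_start < 0:
        raise ValueError("ais_start must be non-negative")
    if ais_length <= 0:
        raise ValueError("ais_length must be positive")
    if channel_config not in ("ais_initiation", "somatic_initiation"):
        raise ValueError(f"unknown channel_config {channel_config!r}")

    segs: list[tuple[np.ndarray, np.ndarray, float, str]] = []

    if include_dendrite:
        # distal dendrite tip first so the chain stays linear
        x_half_soma = SOMA_LENGTH / 2.0
        nodes = np.linspace(
            x_half_soma + DENDRITE_LENGTH, x_half_soma, N_DENDRITE_SEGMENTS + 1
        )
        for a, b in zip(nodes[:-1], nodes[1:]):
            segs.append((np.array([a, 0.0, 0.0]), np.array([b, 0.0, 0.0]),
                         DENDRITE_DIAMETER, "dendrite"))

    # soma: from the +x (dendritic) end toward the axon at −x
    soma_nodes = np.linspace(SOMA_LENGTH / 2.0, -SOMA_LENGTH / 2.0, N_SOMA_SEGMENTS + 1)
    for a, b in zip(soma_nodes[:-1], soma_nodes[1:]):
        segs.append((np.array([a, 0.0, 0.0]), np.array([b, 0.0, 0.0]),
                     SOMA_DIAMETER, "soma"))

    # axon: proximal → distal in −x, re-segmented so AIS edges sit on nodes
    x_axon_root = -SOMA_LENGTH / 2.0
    bp = _axon_breakpoints(ais_start, ais_length)
    ais_end = ais_start + ais_length
    for a, b in zip(bp[:-1], bp[1:]):
        mid = 0.5 * (a + b)
        label = "ais" if (ais_start - 1e-9 < mid < ais_end + 1e-9) else "axon"
        segs.append((
            np.array([x_axon_root - a, 0.0, 0.0]),
            np.array([x_axon_root - b, 0.0, 0.0]),
            AXON_DIAMETER, label,
        ))

    morphology = [
        SegmentGeometry(a, b, d, lab, i) for i, (a, b, d, lab) in enumerate(segs)
    ]

    labels = np.array([s.section_label for s in morphology])
    n = len(morphology)
    gna = np.zeros(n)
    gk = np.zeros(n)
    if channel_config == "ais_initiation":
        gna[labels == "ais"] = DEFAULT_AIS_GNA if gNa is None else gNa
        gk[labels == "ais"] = DEFAULT_AIS_GK if gK is None else gK
    else:
        gna[labels == "soma"] = DEFAULT_SOMA_GNA if gNa is None else gNa
        gk[labels == "soma"] = DEFAULT_SOMA_GK if gK is None else gK
    layout = ChannelLayout(gna, gk, np.full(n, g_leak), E_Na, E_K, E_leak)
    return morphology, layout


def segment_indices(morphology: list[SegmentGeometry], section: str) -> np.ndarray:
    """Indices of all segments carrying the given section label."""
    return np.array([s.index for s in morphology if s.section_label == section], int)


def soma_axon_boundary(morphology: list[SegmentGeometry]) -> int:
    """Index b of the inter-segment boundary (b, b+1) at the soma–axon junction."""
    soma = segment_indices(morphology, "soma")
    if soma.size == 0:
        raise ValueError("morphology has no soma segments")
    b = int(soma.max())
    if b + 1 >= len(morphology):
        raise ValueError("morphology has no axon distal to the soma")
    return b


def ais_proximal_boundary(morphology: list[SegmentGeometry]) -> int:
    """Boundary index just proximal to the first AIS segment."""
    ais = segment_indices(morphology, "ais")
    if ais.size == 0:
        raise ValueError("morphology has no AIS segments")
    return int(ais.min()) - 1


def point_segment_distance(point: np.ndarray, seg: SegmentGeometry) -> float:
    """Euclidean distance from a point to the segment's axis line segment."""
    p = np.asarray(point, float)
    a, b = seg.start_point, seg.end_point
    u = b - a
    t = np.clip(np.dot(p - a, u) / np.dot(u, u), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * u)))


_SWC_TYPES = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}


def read_swc(path: str | Path) -> list[SegmentGeometry]:
    """Read a standard SWC morphology file (geometry only).

    Each non-root SWC point becomes one segment from its parent's
    coordinates to its own; radii are averaged over the two points.
    Imported sections are passive until a :class:`ChannelLayout` is
    supplied by the caller.  Only unbranched chains can be passed to the
    cable solver.
    """
    rows = {}
    order = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        idx = int(parts[0])
        rows[idx] = (int(parts[1]), np.array([float(parts[2]), float(parts[3]),
                                              float(parts[4])]), float(parts[5]),
                     int(parts[6]))
        order.append(idx)

    segs = []
    for idx in order:
        typ, xyz, radius, parent = rows[idx]
        if parent == -1:
            continue
        if parent not in rows:
            raise ValueError(f"SWC point {idx} references unknown parent {parent}")
        _, pxyz, pradius, _ = rows[parent]
        label = _SWC_TYPES.get(typ, "dendrite")
        segs.append(SegmentGeometry(pxyz, xyz, pradius + radius, label, len(segs)))
    if not segs:
        raise ValueError("SWC file contains no segments")
    return segs
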