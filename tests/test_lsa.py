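import numpy as np
import pytest
from scipy.integrate import quad

from aiseap.lsa import (Electrode, FieldRecording, SingularElectrodeError,
                        dipole_potential, electrode_grid, electrode_line,
                        field_from_simulation, line_source_potential,
                        point_source_potential, subtract_baseline)
from aiseap.morphology import SegmentGeometry


def _quad_potential(start, end, I, pos, sigma, tol=1e-12):
    """Brute-force numerical quadrature of the line-source integral."""
    start, end, pos = map(np.asarray, (start, end, pos))
    L = np.linalg.norm(end - start)
    u = (end - start) / L

    def integrand(s):
        return 1.0 / np.linalg.norm(pos - (start + s * u))

    val, _ = quad(integrand, 0.0, L, epsabs=tol, epsrel=tol, limit=500)
    return 1e3 * I / (4 * np.pi * sigma * L) * val


class TestLineSource:
    def test_closed_form_agrees_with_quadrature(self, rng):
        for _ in range(25):
            start = rng.uniform(-40, 40, 3)
            end = start + rng.uniform(-30, 30, 3)
            if np.linalg.norm(end - start) < 1.0:
                continue
            pos = rng.uniform(-200, 200, 3)
            seg = SegmentGeometry(start, end, 1.0, "axon", 0)
            # keep clear of the singular segment itself
            from aiseap.morphology import point_segment_distance
            if point_segment_distance(pos, seg) < 1.0:
                continue
            got = line_source_potential(seg, 2.5, Electrode(pos), 0.3)
            want = _quad_potential(start, end, 2.5, pos, 0.3)
            assert got == pytest.approx(want, rel=1e-6)

    def test_on_axis_beyond_ends_is_finite_and_exact(self):
        seg = SegmentGeometry([0, 0, 0], [10, 0, 0], 1.0, "axon", 0)
        got = line_source_potential(seg, 1.0, Electrode(np.array([25.0, 0, 0])))
        want = _quad_potential([0, 0, 0], [10, 0, 0], 1.0, [25.0, 0, 0], 0.3)
        assert np.isfinite(got)
        assert got == pytest.approx(want, rel=1e-9)

    def test_point_source_limit_far_away(self):
        """At r = 100 L on the perpendicular bisector the line source
        matches a point source to 0.01%."""
        L = 10.0
        seg = SegmentGeometry([-L / 2, 0, 0], [L / 2, 0, 0], 1.0, "axon", 0)
        r = 100 * L
        v_line = line_source_potential(seg, 1.0, Electrode(np.array([0, r, 0])))
        v_point = point_source_potential(1.0, r)
        assert v_line == pytest.approx(v_point, rel=1e-4)

    def test_reflection_symmetry_across_bisector(self):
        seg = SegmentGeometry([0, 0, 0], [10, 0, 0], 1.0, "axon", 0)
        a = line_source_potential(seg, 1.0, Electrode(np.array([2.0, 7.0, 0])))
        b = line_source_potential(seg, 1.0, Electrode(np.array([8.0, 7.0, 0])))
        assert a == pytest.approx(b, rel=1e-12)

    def test_electrode_on_segment_raises(self):
        seg = SegmentGeometry([0, 0, 0], [10, 0, 0], 1.0, "axon", 0)
        with pytest.raises(SingularElectrodeError):
            line_source_potential(seg, 1.0, Electrode(np.array([5.0, 0, 0])))


def test_point_source_kernel_reciprocity(rng):
    """Swapping source and electrode positions leaves the kernel unchanged."""
    a, b = rng.uniform(-100, 100, (2, 3))
    r = np.linalg.norm(a - b)
    assert point_source_potential(1.0, r) == point_source_potential(
        1.0, np.linalg.norm(b - a))


class TestDipolePotential:
    def test_perpendicular_plane_is_zero(self):
        assert dipole_potential(1.0, 50.0, 200.0, np.pi / 2) == pytest.approx(0.0)

    def test_inverse_square(self):
        v1 = dipole_potential(1.0, 50.0, 100.0, 0.0)
        v2 = dipole_potential(1.0, 50.0, 200.0, 0.0)
        assert v1 / v2 == pytest.approx(4.0)

    def test_hand_evaluated_example(self):
        # I·d/(4πσr²) with I=1 nA, d=50 μm, σ=0.3 S/m, r=100 μm
        want = 1e3 * 1.0 * 50.0 / (4 * np.pi * 0.3 * 100.0**2)
        assert dipole_potential(1.0, 50.0, 100.0, 0.0, 0.3) == pytest.approx(want)
        assert want == pytest.approx(1.3263, abs=1e-4)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            dipole_potential(1.0, 50.0, 0.0, 0.0)


class TestFieldFromSimulation:
    def test_zero_currents_give_zero_field(self, sim_ais45):
        res = sim_ais45
        silent = type(res)(time=res.time, Vm=res.Vm,
                           I_membrane=np.zeros_like(res.I_membrane),
                           I_axial=res.I_axial, morphology=res.morphology,
                           layout=res.layout, passive=res.passive,
                           stimulus=res.stimulus, dt=res.dt)
        rec = field_from_simulation(silent, [Electrode(np.array([0, 50, 0]))])
        assert np.all(rec.V_ext == 0)

    def test_linearity_doubling_currents(self, sim_ais45):
        el = [Electrode(np.array([0, 60, 0])), Electrode(np.array([120, 0, 0]))]
        rec1 = field_from_simulation(sim_ais45, el)
        doubled = type(sim_ais45)(
            time=sim_ais45.time, Vm=sim_ais45.Vm,
            I_membrane=2 * sim_ais45.I_membrane, I_axial=sim_ais45.I_axial,
            morphology=sim_ais45.morphology, layout=sim_ais45.layout,
            passive=sim_ais45.passive, stimulus=sim_ais45.stimulus,
            dt=sim_ais45.dt)
        rec2 = field_from_simulation(doubled, el)
        assert np.allclose(rec2.V_ext, 2 * rec1.V_ext)

    def test_superposition_over_segments(self, sim_ais45):
        """The summed field equals the sum of per-segment line sources."""
        el = Electrode(np.array([40.0, 55.0, 0.0]))
        rec = field_from_simulation(sim_ais45, [el])
        k = sim_ais45.time.size // 2
        total = sum(
            line_source_potential(seg, sim_ais45.I_membrane[i, k], el)
            for i, seg in enumerate(sim_ais45.morphology))
        assert rec.V_ext[0, k] == pytest.approx(total, rel=1e-10)

    def test_segment_count_mismatch_rejected(self, sim_ais45):
        with pytest.raises(ValueError):
            field_from_simulation(sim_ais45, [Electrode(np.array([0, 50, 0]))],
                                  morphology=sim_ais45.morphology[:-1])


class TestSubtractBaseline:
    def _recording(self, trace):
        t = np.arange(trace.size) * 0.1
        return FieldRecording([Electrode(np.array([0, 50, 0]))], t,
                              trace[None, :])

    def test_constant_trace_becomes_zero(self):
        rec = self._recording(np.full(100, 3.7))
        out = subtract_baseline(rec, 5.0)
        assert np.allclose(out.V_ext, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        rec = self._recording(rng.normal(size=200))
        once = subtract_baseline(rec, 10.0)
        twice = subtract_baseline(once, 10.0)
        assert np.allclose(once.V_ext, twice.V_ext, atol=1e-12)

    def test_ramp_hand_check(self):
        t = np.arange(0, 10.0 + 1e-9, 0.1)
        trace = 2.0 * t  # window [3, 4] has mean 7
        rec = FieldRecording([Electrode(np.array([0, 50, 0]))], t,
                             trace[None, :])
        out = subtract_baseline(rec, 5.0)
        assert out.V_ext[0, 0] == pytest.approx(-7.0)
        assert out.V_ext[0, -1] == pytest.approx(20.0 - 7.0)

    def test_window_outside_range_rejected(self):
        rec = self._recording(np.zeros(50))  # 0..4.9 ms
        with pytest.raises(ValueError):
            subtract_baseline(rec, 1.0)


def test_electrode_line_and_grid_builders():
    line = electrode_line("y", 50.0, 1000.0, 20, spacing="log")
    rs = [np.linalg.norm(e.position) for e in line]
    assert rs[0] == pytest.approx(50.0)
    assert rs[-1] == pytest.approx(1000.0)
    assert np.allclose(np.diff(np.log(rs)), np.log(rs[1] / rs[0]))
    grid = electrode_grid((-10, 10), (5, 25), 3, 4)
    assert len(grid) == 12
    with pytest.raises(ValueError):
        electrode_line("x", 0.0, 100.0, 5, spacing="log")


def test_field_recording_text_export_roundtrip(tmp_path, sim_ais45):
    el = [Electrode(np.array([0, 60, 0]), "a"), Electrode(np.array([90, 0, 0]), "b")]
    rec = field_from_simulation(sim_ais45, el)
    path = tmp_path / "rec.tsv"
    rec.to_text(path)
    data = np.loadtxt(path, skiprows=1)
    assert np.allclose(data[:, 0], rec.time)
    assert np.allclose(data[:, 1:].T, rec.V_ext)
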