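"""Pore axis, traversal detection, conductance, and D_z traces."""

import numpy as np
import pytest

from poreflux.io import select
from poreflux.permeation import (SF_AXIAL_OFFSET, compute_pore_axis,
                                 conductance, detect_permeation_events,
                                 dz_trace, ion_cylindrical_coords)
from poreflux.synth import SyntheticSpec, gen_ion_channel_traj
from tests.conftest import static_trajectory, system_from_rows


def _toy_ion_traj(z_path, box=(60.0, 60.0, 80.0)):
    """One SF pair (masses put the COM at the origin) plus one ion following
    ``z_path`` (raw z relative to the SF centre at z=40)."""
    rows = [("CA", "GLY", 1, "A", "C", 12.011), ("CA", "GLY", 2, "B", "C", 12.011),
            ("K", "K", 10, "I", "K", 39.0983)]
    system = system_from_rows(rows)
    n = len(z_path)
    coords = np.zeros((n, 3, 3))
    coords[:, 0] = [28.0, 30.0, 40.0]
    coords[:, 1] = [32.0, 30.0, 40.0]
    coords[:, 2, 0] = 30.0
    coords[:, 2, 1] = 30.0
    coords[:, 2, 2] = 40.0 + np.asarray(z_path)
    from poreflux.io import Trajectory
    return Trajectory(system=system, times=np.arange(1, n + 1, dtype=float),
                      coords=coords, boxes=np.tile(np.asarray(box), (n, 1)))


class TestPoreAxis:
    def test_static_sf_center_reported_at_7(self):
        traj = _toy_ion_traj([0.0] * 3)
        axis = compute_pore_axis(traj, np.array([0, 1]))
        np.testing.assert_allclose(axis[0].origin, [30.0, 30.0, 40.0])
        dz, _ = ion_cylindrical_coords(traj, 2, axis)
        np.testing.assert_allclose(dz, SF_AXIAL_OFFSET)

    def test_translation_moves_origin_not_dz(self):
        traj = _toy_ion_traj(np.linspace(-5, 5, 7))
        t2 = _toy_ion_traj(np.linspace(-5, 5, 7))
        t2.coords += np.array([5.0, 5.0, 5.0])
        a1 = compute_pore_axis(traj, np.array([0, 1]))
        a2 = compute_pore_axis(t2, np.array([0, 1]))
        np.testing.assert_allclose(a2[0].origin - a1[0].origin, [5, 5, 5])
        dz1, _ = ion_cylindrical_coords(traj, 2, a1)
        dz2, _ = ion_cylindrical_coords(t2, 2, a2)
        np.testing.assert_allclose(dz1, dz2, atol=1e-12)

    def test_mass_weighted_center(self):
        rows = [("N", "GLY", 1, "A", "H", 1.0), ("CA", "GLY", 1, "A", "C", 3.0)]
        system = system_from_rows(rows)
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]])
        traj = static_trajectory(system, coords)
        axis = compute_pore_axis(traj, np.array([0, 1]))
        assert axis[0].origin[2] == pytest.approx(3.0)

    def test_empty_selection_rejected(self):
        traj = _toy_ion_traj([0.0])
        with pytest.raises(ValueError):
            compute_pore_axis(traj, np.array([], dtype=int))


class TestDetection:
    LOWER, UPPER = -1.0, 15.0

    def _detect(self, traj):
        axis = compute_pore_axis(traj, np.array([0, 1]))
        return detect_permeation_events(traj, np.array([2]), axis,
                                        self.LOWER, self.UPPER)

    def test_single_traversal_one_outward_event(self):
        z = np.linspace(-14, 14, 20)  # raw: reported -7 .. 21, crosses both planes
        events = self._detect(_toy_ion_traj(z))
        assert len(events) == 1
        assert events[0].direction == "outward"
        assert not events[0].undersampled

    def test_reverse_traversal_inward(self):
        events = self._detect(_toy_ion_traj(np.linspace(14, -14, 20)))
        assert len(events) == 1 and events[0].direction == "inward"

    def test_oscillation_across_one_plane_only(self):
        # reported dz oscillates around the lower plane, never nears the upper
        z = -8.0 + 3.0 * np.sin(np.linspace(0, 8 * np.pi, 200))
        assert self._detect(_toy_ion_traj(z)) == []

    def test_reentry_without_traversal_not_counted(self):
        # enters from below, retreats, then traverses: exactly one event
        z = np.concatenate([np.linspace(-12, 2, 10), np.linspace(2, -12, 10),
                            np.linspace(-12, 14, 20)])
        events = self._detect(_toy_ion_traj(z))
        assert len(events) == 1

    def test_single_step_jump_flagged_undersampled(self):
        z = np.array([-12.0, -12.0, 14.0, 14.0])
        events = self._detect(_toy_ion_traj(z))
        assert len(events) == 1 and events[0].undersampled

    def test_pbc_wrap_not_a_traversal(self):
        # ion drifts past the box top and wraps to the bottom image
        z = np.concatenate([np.linspace(20, 39, 10), np.linspace(-39, -20, 10)])
        assert self._detect(_toy_ion_traj(z)) == []

    def test_outside_cylinder_never_counts(self):
        traj = _toy_ion_traj(np.linspace(-14, 14, 20))
        traj.coords[:, 2, 0] += 12.0  # radially outside the 8 Å gate
        assert self._detect(traj) == []

    def test_detector_recovers_planted_counts(self):
        for seed in range(10):
            spec = SyntheticSpec(seed=seed, duration=300, dt=0.5,
                                 permeation_rate=8.0)
            traj, planted = gen_ion_channel_traj(spec)
            axis = compute_pore_axis(traj, select(traj.system, "name N CA C O"))
            events = detect_permeation_events(
                traj, select(traj.system, "name K"), axis, self.LOWER, self.UPPER)
            assert len(events) == len(planted)
            assert all(e.direction == "outward" for e in events)

    def test_stride_refinement_invariance(self):
        spec = SyntheticSpec(seed=9, duration=300, dt=0.5, permeation_rate=8.0)
        traj, planted = gen_ion_channel_traj(spec)
        sf = select(traj.system, "name N CA C O")
        ions = select(traj.system, "name K")
        from poreflux.io import Trajectory
        sub = Trajectory(system=traj.system, times=traj.times[::2],
                         coords=traj.coords[::2], boxes=traj.boxes[::2])
        n1 = len(detect_permeation_events(traj, ions,
                                          compute_pore_axis(traj, sf),
                                          self.LOWER, self.UPPER))
        n2 = len(detect_permeation_events(sub, ions,
                                          compute_pore_axis(sub, sf),
                                          self.LOWER, self.UPPER))
        assert n1 == n2 == len(planted)


class TestConductance:
    def test_paper_regime_five_events_1us_200mV(self):
        assert conductance(5, 1000.0, 200.0) == pytest.approx(4.005, abs=5e-3)

    def test_zero_events(self):
        assert conductance(0, 1000.0, 200.0) == 0.0

    def test_doubling_time_halves_gamma(self):
        assert conductance(5, 2000.0, 200.0) == pytest.approx(
            conductance(5, 1000.0, 200.0) / 2)

    def test_hand_formula_agreement(self):
        g = conductance(7, 1234.5, 150.0)
        hand = 7 * 1.602176634e-19 / (1234.5e-9 * 0.150) * 1e12
        assert g == pytest.approx(hand, rel=1e-12)

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            conductance(5, 1000.0, 0.0)


class TestDzTrace:
    def test_coincident_reference_zero(self):
        rows = [("P", "POPC", 1, "M", "P", 30.974), ("C12", "LIG", 2, "L", "C", 12.011)]
        system = system_from_rows(rows)
        coords = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 5.0]])
        traj = static_trajectory(system, coords)
        _, dz = dz_trace(traj, np.array([1]), np.array([0]))
        assert dz[0] == pytest.approx(0.0)

    def test_ten_angstrom_offset(self):
        rows = [("P", "POPC", 1, "M", "P", 30.974), ("C12", "LIG", 2, "L", "C", 12.011)]
        system = system_from_rows(rows)
        coords = np.array([[0.0, 0.0, 5.0], [3.0, 4.0, 15.0]])
        traj = static_trajectory(system, coords)
        _, dz = dz_trace(traj, np.array([1]), np.array([0]))
        assert dz[0] == pytest.approx(10.0)

    def test_planted_drift_recovered(self):
        rng = np.random.default_rng(0)
        n = 400
        rows = [("P", "POPC", 1, "M", "P", 30.974), ("C12", "LIG", 2, "L", "C", 12.011)]
        system = system_from_rows(rows)
        coords = np.zeros((n, 2, 3))
        coords[:, 0, 2] = 5.0
        drift = np.linspace(0, -8.0, n)
        coords[:, 1, 2] = 15.0 + drift + rng.normal(0, 0.2, n)
        from poreflux.io import Trajectory
        traj = Trajectory(system=system, times=np.arange(1, n + 1, dtype=float),
                          coords=coords, boxes=np.tile([100.0] * 3, (n, 1)))
        t, dz = dz_trace(traj, np.array([1]), np.array([0]))
        slope = np.polyfit(t, dz, 1)[0] * (t[-1] - t[0])
        assert slope == pytest.approx(-8.0, rel=0.05)
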