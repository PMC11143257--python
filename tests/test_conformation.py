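"""ψ dihedrals, flip classification, circular KDE, and the M4 θ-angle."""

import numpy as np
import pytest

from poreflux.conformation import (angle_distribution, classify_flips,
                                   dihedral_angle, helix_vector, m4_theta,
                                   psi_series)
from poreflux.io import Trajectory
from poreflux.synth import SyntheticSpec, gen_dihedral_series
from tests.conftest import make_backbone_chain, static_trajectory, system_from_rows


def _four_points_with_dihedral(psi_deg: float):
    """Exact-geometry construction: returns p0..p3 whose signed dihedral is
    ``psi_deg`` (verified analytically: the first half-plane direction is +x,
    the second is at azimuth −ψ, and the sign convention flips it back)."""
    r = np.radians(-psi_deg)
    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([0.0, 0.0, 1.5])
    p0 = np.array([1.4, 0.0, -0.5])
    p3 = p2 + np.array([1.4 * np.cos(r), 1.4 * np.sin(r), 0.5])
    return p0, p1, p2, p3


def _psi_trajectory(psi_deg: float):
    """Two residues (1 and 2, chain A) whose ψ(resid 1) equals psi_deg."""
    p0, p1, p2, p3 = _four_points_with_dihedral(psi_deg)
    rows = [("N", "GLY", 1, "A", "N", 14.007), ("CA", "GLY", 1, "A", "C", 12.011),
            ("C", "GLY", 1, "A", "C", 12.011), ("N", "GLY", 2, "A", "N", 14.007),
            ("CA", "GLY", 2, "A", "C", 12.011)]
    system = system_from_rows(rows)
    coords = np.array([p0, p1, p2, p3, p3 + [1.0, 0.0, 0.0]])
    return static_trajectory(system, coords, n_frames=2)


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


class TestPsi:
    @pytest.mark.parametrize("psi", [120.0, -120.0, 60.0, 179.0, -45.0])
    def test_constructed_geometry_exact(self, psi):
        traj = _psi_trajectory(psi)
        series = psi_series(traj, "A", 1)
        assert series.psi[0] == pytest.approx(psi, abs=1e-6)

    def test_mirror_inverts_sign(self):
        traj = _psi_trajectory(120.0)
        traj.coords[..., 1] *= -1
        series = psi_series(traj, "A", 1)
        assert series.psi[0] == pytest.approx(-120.0, abs=1e-6)

    def test_rigid_rotation_invariance(self):
        traj = _psi_trajectory(75.0)
        Q = _random_rotation(4)
        traj.coords = traj.coords @ Q.T + np.array([3.0, -2.0, 9.0])
        series = psi_series(traj, "A", 1)
        assert series.psi[0] == pytest.approx(75.0, abs=1e-9)

    def test_chain_terminal_residue_rejected(self):
        traj = _psi_trajectory(120.0)
        with pytest.raises(ValueError):
            psi_series(traj, "A", 2)


class TestFlips:
    def test_constant_inside_band(self):
        s = classify_flips(np.full(100, -42.0), band_center=-40.0)
        assert s.flip_fraction == 0.0 and s.first_flip_time is None

    def test_constant_outside_band(self):
        s = classify_flips(np.full(100, 140.0), band_center=-40.0,
                           times=np.arange(100, dtype=float))
        assert s.flip_fraction == 1.0
        assert s.first_flip_time == 0.0

    def test_telegraph_fixture_within_1pct(self):
        spec = SyntheticSpec(seed=6, duration=4000, dt=0.5, flip_rate=4.0)
        _, psi, labels = gen_dihedral_series(spec, state_means=(-40.0, 140.0),
                                             noise_sd=8.0)
        s = classify_flips(psi, band_center=-40.0, band_half_width=60.0)
        assert abs(s.flip_fraction - labels.mean()) < 0.01

    def test_zero_hysteresis_is_plain_membership(self):
        rng = np.random.default_rng(1)
        psi = rng.uniform(-180, 180, 500)
        s = classify_flips(psi, band_center=0.0, band_half_width=40.0,
                           hysteresis=0.0)
        plain = (np.abs(psi) > 40.0).astype(int)
        np.testing.assert_array_equal(s.states, plain)

    def test_hysteresis_suppresses_edge_chatter(self):
        # series hovering on the band edge: with hysteresis, no switching
        psi = np.array([0.0] + [39.0, 41.0] * 50)
        s = classify_flips(psi, band_center=0.0, band_half_width=40.0,
                           hysteresis=10.0)
        assert s.flip_fraction == 0.0

    def test_band_membership_is_circular(self):
        s = classify_flips(np.full(10, -178.0), band_center=178.0,
                           band_half_width=10.0)
        assert s.flip_fraction == 0.0


class TestAngleDistribution:
    def test_point_mass_single_mode(self):
        g, d = angle_distribution(np.full(50, 30.0) +
                                  np.random.default_rng(0).normal(0, 0.5, 50),
                                  bandwidth=2.0)
        assert abs(g[np.argmax(d)] - 30.0) <= 2.0

    def test_normalized_over_circle(self):
        rng = np.random.default_rng(1)
        g, d = angle_distribution(rng.uniform(-180, 180, 400), bandwidth=15.0)
        assert np.trapezoid(d, g) == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_modes_recovered(self):
        spec = SyntheticSpec(seed=8, duration=4000, dt=0.5, flip_rate=5.0)
        _, psi, _ = gen_dihedral_series(spec, state_means=(-40.0, 140.0),
                                        noise_sd=6.0)
        g, d = angle_distribution(psi, bandwidth=6.0,
                                  grid=np.linspace(-180, 180, 721))
        # two planted means: local maxima within 2°
        for mean in (-40.0, 140.0):
            window = np.abs(g - mean) <= 15.0
            assert abs(g[window][np.argmax(d[window])] - mean) <= 2.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            angle_distribution(np.array([10.0]))


def _helix_traj():
    rows, coords = make_backbone_chain("A", range(315, 334))
    system = system_from_rows(rows)
    return static_trajectory(system, coords, n_frames=2), coords


class TestTheta:
    def test_identity_zero(self):
        traj, ref = _helix_traj()
        ho = m4_theta(traj, "A", ref)
        np.testing.assert_allclose(ho.theta, 0.0, atol=1e-9)

    def test_15_degree_rotation(self):
        traj, ref = _helix_traj()
        v = helix_vector(ref, traj.system, "A")
        # axis through Cα(315) perpendicular to the helix vector
        u = np.cross(v, [0.0, 0.0, 1.0])
        u /= np.linalg.norm(u)
        ca315 = ref[np.flatnonzero(
            (traj.system.residue_ids == 315) &
            (traj.system.atom_names.astype(str) == "CA"))[0]]
        ang = np.radians(15.0)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        traj.coords = (traj.coords - ca315) @ R.T + ca315
        ho = m4_theta(traj, "A", ref)
        np.testing.assert_allclose(ho.theta, 15.0, atol=1e-6)

    def test_translation_only_zero(self):
        traj, ref = _helix_traj()
        traj.coords += np.array([5.0, -3.0, 11.0])
        ho = m4_theta(traj, "A", ref)
        np.testing.assert_allclose(ho.theta, 0.0, atol=1e-9)

    def test_global_rotation_of_both_invariant(self):
        traj, ref = _helix_traj()
        Q = _random_rotation(7)
        traj.coords = traj.coords @ Q.T
        ho = m4_theta(traj, "A", ref @ Q.T)
        np.testing.assert_allclose(ho.theta, 0.0, atol=1e-9)

    def test_selection_mismatch_rejected(self):
        traj, ref = _helix_traj()
        with pytest.raises(ValueError):
            m4_theta(traj, "B", ref)
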