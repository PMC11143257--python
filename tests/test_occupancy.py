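"""Occupancy binning, the volume/time normalization, and site assignment."""

import numpy as np
import pytest

from poreflux.io import Trajectory
from poreflux.occupancy import (assign_sites, default_sites, occupancy_profile,
                                SiteDefinition)
from poreflux.permeation import PoreAxisFrame, SF_AXIAL_OFFSET
from tests.conftest import system_from_rows


def _ion_traj(positions, n_frames=None, box=(60.0, 60.0, 80.0), dt=1.0):
    """Trajectory of free ions at given raw positions (n_frames, n_ions, 3)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    if n_frames is not None and positions.shape[0] == 1:
        positions = np.repeat(positions, n_frames, axis=0)
    nf, ni, _ = positions.shape
    rows = [("K", "K", 100 + i, "I", "K", 39.0983) for i in range(ni)]
    system = system_from_rows(rows)
    return Trajectory(system=system, times=(np.arange(nf) + 1) * dt,
                      coords=positions, boxes=np.tile(np.asarray(box), (nf, 1)))


def _axis(n_frames, radius=8.0):
    return [PoreAxisFrame(origin=np.array([30.0, 30.0, 40.0]),
                          axis=np.array([0.0, 0.0, 1.0]), radius=radius)
            for _ in range(n_frames)]


class TestNormalization:
    def test_parked_ion_closed_form(self):
        # one static ion at reported z = 7 for 100 frames of 1 ns
        nf = 100
        traj = _ion_traj([[[30.0, 30.0, 40.0]]], n_frames=nf)
        axis = _axis(nf)
        z_edges = np.linspace(2.0, 12.0, 11)   # 1 Å bins
        grid = occupancy_profile(traj, np.array([0]), axis, z_edges,
                                 total_time_ns=100.0)
        assert grid.counts.sum() == nf
        hot = np.flatnonzero(grid.counts)
        assert len(hot) == 1
        bin_vol = np.pi * 8.0 ** 2 * 1.0
        expected = nf / (bin_vol / 0.001) / (100.0 / 1000.0)
        assert grid.density[hot[0]] == pytest.approx(expected, rel=1e-12)

    def test_uniform_ions_flat_1d(self):
        rng = np.random.default_rng(0)
        nf, ni = 400, 25
        r = 8.0 * np.sqrt(rng.random((nf, ni)))
        th = rng.uniform(0, 2 * np.pi, (nf, ni))
        z = rng.uniform(-5.0, 5.0, (nf, ni))
        pos = np.stack([30.0 + r * np.cos(th), 30.0 + r * np.sin(th), 40.0 + z],
                       axis=-1)
        traj = _ion_traj(pos)
        z_edges = np.linspace(SF_AXIAL_OFFSET - 5.0, SF_AXIAL_OFFSET + 5.0, 11)
        grid = occupancy_profile(traj, np.arange(ni), _axis(nf), z_edges)
        expected = grid.counts.mean()
        sd = np.sqrt(expected)
        assert np.all(np.abs(grid.counts - expected) <= 3 * sd)

    def test_uniform_ions_r_independent_2d(self):
        rng = np.random.default_rng(1)
        nf, ni = 400, 25
        r = 8.0 * np.sqrt(rng.random((nf, ni)))   # uniform in area
        th = rng.uniform(0, 2 * np.pi, (nf, ni))
        z = rng.uniform(-5.0, 5.0, (nf, ni))
        pos = np.stack([30.0 + r * np.cos(th), 30.0 + r * np.sin(th), 40.0 + z],
                       axis=-1)
        traj = _ion_traj(pos)
        z_edges = np.linspace(2.0, 12.0, 3)
        r_edges = np.linspace(0.0, 8.0, 5)
        grid = occupancy_profile(traj, np.arange(ni), _axis(nf), z_edges, r_edges)
        # annular volume correction: density per 0.001 Å³ should not trend in r
        ann_vol = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) * np.diff(z_edges)[0]
        for zi in range(2):
            dens = grid.density[zi]
            counts = grid.counts[zi]
            sd = 3 * np.sqrt(np.maximum(counts, 1)) / (ann_vol / 0.001) / \
                (grid.total_time_ns / 1000.0)
            assert np.all(np.abs(dens - dens.mean()) <= sd + 1e-12)

    def test_doubling_time_same_density(self):
        nf = 50
        traj1 = _ion_traj([[[30.0, 30.0, 40.0]]], n_frames=nf, dt=1.0)
        traj2 = _ion_traj([[[30.0, 30.0, 40.0]]], n_frames=2 * nf, dt=1.0)
        z_edges = np.linspace(2.0, 12.0, 11)
        g1 = occupancy_profile(traj1, np.array([0]), _axis(nf), z_edges,
                               total_time_ns=nf)
        g2 = occupancy_profile(traj2, np.array([0]), _axis(2 * nf), z_edges,
                               total_time_ns=2 * nf)
        np.testing.assert_allclose(g1.density, g2.density)

    def test_bin_refinement_conserves_counts(self):
        rng = np.random.default_rng(2)
        nf, ni = 100, 10
        pos = np.stack([30.0 + rng.uniform(-4, 4, (nf, ni)),
                        30.0 + rng.uniform(-4, 4, (nf, ni)),
                        40.0 + rng.uniform(-4.9, 4.9, (nf, ni))], axis=-1)
        traj = _ion_traj(pos)
        coarse = occupancy_profile(traj, np.arange(ni), _axis(nf),
                                   np.linspace(2, 12, 6))
        fine = occupancy_profile(traj, np.arange(ni), _axis(nf),
                                 np.linspace(2, 12, 51))
        assert coarse.counts.sum() == fine.counts.sum()

    def test_zero_time_rejected(self):
        traj = _ion_traj([[[30.0, 30.0, 40.0]]], n_frames=1)
        with pytest.raises(ValueError):
            occupancy_profile(traj, np.array([0]), _axis(1),
                              np.linspace(2, 12, 5), total_time_ns=0.0)


class TestSites:
    def test_default_sites_geometry(self):
        sites = default_sites()
        assert sites.labels == ["S0", "S1", "S2", "S3", "S4", "S5"]
        # SF centre (z = 7) is the S2/S3 boundary; S0 most extracellular
        s2 = sites.intervals[2]
        s3 = sites.intervals[3]
        assert s3[1] == pytest.approx(7.0) and s2[0] == pytest.approx(7.0)
        assert sites.intervals[0][1] > sites.intervals[5][1]

    def test_parked_ion_fills_one_site(self):
        nf = 80
        # reported z = 8.0 -> inside S2 = [7.0, 10.4)
        traj = _ion_traj([[[30.0, 30.0, 41.0]]], n_frames=nf)
        grid = occupancy_profile(traj, np.array([0]), _axis(nf),
                                 np.linspace(-3.2, 17.2, 103), total_time_ns=nf)
        table = assign_sites(grid, default_sites(), n_frames=nf)
        occ = dict(zip(table.site, table.mean_occupancy))
        assert occ["S2"] == pytest.approx(1.0)
        for s in ("S0", "S1", "S3", "S4", "S5"):
            assert occ[s] == 0.0

    def test_two_parked_ions_two_sites(self):
        nf = 40
        traj = _ion_traj([[[30.0, 30.0, 41.0], [30.0, 30.0, 35.0]]], n_frames=nf)
        grid = occupancy_profile(traj, np.arange(2), _axis(nf),
                                 np.linspace(-3.2, 17.2, 103), total_time_ns=nf)
        table = assign_sites(grid, default_sites(), n_frames=nf)
        occ = dict(zip(table.site, table.mean_occupancy))
        assert occ["S2"] == pytest.approx(1.0)
        assert occ["S4"] == pytest.approx(1.0)   # reported z = 2 in [0.2, 3.6)

    def test_planted_site_suppression_ratio(self):
        # up-like: ions spread over S1-S4; down-like: S1/S4 depleted
        rng = np.random.default_rng(3)
        nf = 500
        site_z = {"S1": 12.0, "S2": 8.5, "S3": 5.0, "S4": 2.0}

        def traj_for(weights):
            zs = rng.choice([site_z[s] for s in ("S1", "S2", "S3", "S4")],
                            size=(nf, 4), p=weights)
            pos = np.stack([np.full((nf, 4), 30.0), np.full((nf, 4), 30.0),
                            40.0 + zs - 7.0], axis=-1)
            return _ion_traj(pos)

        up = traj_for([0.25, 0.25, 0.25, 0.25])
        down = traj_for([0.02, 0.48, 0.48, 0.02])
        edges = np.linspace(-3.2, 17.2, 103)
        t_up = assign_sites(occupancy_profile(up, np.arange(4), _axis(nf), edges,
                                              total_time_ns=nf),
                            default_sites(), n_frames=nf)
        t_dn = assign_sites(occupancy_profile(down, np.arange(4), _axis(nf), edges,
                                              total_time_ns=nf),
                            default_sites(), n_frames=nf)
        occ_up = dict(zip(t_up.site, t_up.mean_occupancy))
        occ_dn = dict(zip(t_dn.site, t_dn.mean_occupancy))
        for s in ("S1", "S4"):
            assert occ_dn[s] / occ_up[s] < 0.2

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            SiteDefinition(labels=["S0", "S1"], intervals=[(0.0, 4.0), (3.0, 6.0)])
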