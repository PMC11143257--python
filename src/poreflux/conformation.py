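"""Backbone ψ dihedrals, carbonyl-flip classification, circular angle
densities, and the M4 helix θ-angle against a reference structure.

A carbonyl flip is tracked through the ψ dihedral of the filter residue: the
frame is "crystallographic" while ψ stays (circularly) inside a band around
the reference value and "flipped" outside it, with hysteresis at the band
edges so noise at the boundary does not chatter between states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ParticleSystem, Trajectory
from .synth import wrap_angle

__all__ = [
    "DihedralSeries",
    "FlipSummary",
    "HelixOrientation",
    "dihedral_angle",
    "psi_series",
    "classify_flips",
    "angle_distribution",
    "m4_theta",
]


@dataclass
class DihedralSeries:
    residue: tuple          # (chain, resid, resname)
    times: np.ndarray       # ns
    psi: np.ndarray         # degrees, (−180, 180]


@dataclass
class FlipSummary:
    states: np.ndarray        # 0 = crystallographic, 1 = flipped
    flip_fraction: float
    first_flip_time: float | None
    mean_dwell_crys: float    # ns; nan if never occupied
    mean_dwell_flip: float


@dataclass
class HelixOrientation:
    times: np.ndarray
    theta: np.ndarray           # degrees in [0, 180]
    reference_vector: np.ndarray


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees) of four points, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_indices(system: ParticleSystem, chain: str, resid: int):
    sel = (system.chain_ids.astype(str) == chain) & (system.residue_ids == resid)
    out = {}
    for name in ("N", "CA", "C"):
        idx = np.flatnonzero(sel & (system.atom_names.astype(str) == name))
        if idx.size != 1:
            raise ValueError(f"residue {chain}:{resid} lacks a unique backbone {name}")
        out[name] = int(idx[0])
    return out


def psi_series(trajectory: Trajectory, chain: str, resid: int) -> DihedralSeries:
    """ψ(t) of a residue: the N–Cα–C–N(next) torsion per frame.

    Raises for a chain-terminal residue (no following N on the same chain).
    """
    system = trajectory.system
    bb = _backbone_indices(system, chain, resid)
    sel_next = (system.chain_ids.astype(str) == chain) & \
        (system.residue_ids == resid + 1) & (system.atom_names.astype(str) == "N")
    idx_next = np.flatnonzero(sel_next)
    if idx_next.size != 1:
        raise ValueError(
            f"residue {chain}:{resid} has no successor N (chain-terminal?)"
        )
    i_n, i_ca, i_c, i_nn = bb["N"], bb["CA"], bb["C"], int(idx_next[0])
    psi = np.array([
        dihedral_angle(trajectory.coords[f, i_n], trajectory.coords[f, i_ca],
                       trajectory.coords[f, i_c], trajectory.coords[f, i_nn])
        for f in range(trajectory.n_frames)
    ])
    resname = str(system.residue_names[np.flatnonzero(
        (system.chain_ids.astype(str) == chain) & (system.residue_ids == resid))[0]])
    return DihedralSeries(residue=(chain, resid, resname),
                          times=trajectory.times.copy(), psi=wrap_angle(psi))


def _in_band(angle, center, half_width):
    return np.abs(wrap_angle(np.asarray(angle) - center)) <= half_width


def classify_flips(
    series_or_psi,
    band_center: float,
    band_half_width: float = 40.0,
    hysteresis: float = 10.0,
    times: np.ndarray | None = None,
) -> FlipSummary:
    """Classify each frame as crystallographic (ψ inside the band, circular
    membership) or flipped, with edge hysteresis.

    A frame switches crystallographic → flipped only once ψ leaves the band
    widened by ``hysteresis``; flipped → crystallographic only once ψ enters
    the band narrowed by it.  Zero hysteresis reduces to plain membership.
    """
    if 2 * band_half_width >= 180.0:
        raise ValueError("band width must be < 180°")
    if isinstance(series_or_psi, DihedralSeries):
        psi = series_or_psi.psi
        times = series_or_psi.times
    else:
        psi = np.asarray(series_or_psi, dtype=float)
        if times is None:
            times = np.arange(len(psi), dtype=float)
    n = len(psi)
    states = np.zeros(n, dtype=int)
    inside_wide = _in_band(psi, band_center, band_half_width + hysteresis)
    inside_narrow = _in_band(psi, band_center, max(band_half_width - hysteresis, 0.0))
    inside_plain = _in_band(psi, band_center, band_half_width)
    state = 0 if inside_plain[0] else 1
    states[0] = state
    for f in range(1, n):
        if state == 0 and not inside_wide[f]:
            state = 1
        elif state == 1 and inside_narrow[f]:
            state = 0
        states[f] = state
    flip_fraction = float(states.mean())
    flipped_idx = np.flatnonzero(states == 1)
    first_flip = float(times[flipped_idx[0]]) if flipped_idx.size else None

    def mean_dwell(target):
        runs, run = [], 0
        for s in states:
            if s == target:
                run += 1
            elif run:
                runs.append(run)
                run = 0
        if run:
            runs.append(run)
        if not runs:
            return float("nan")
        dt = (times[-1] - times[0]) / (n - 1) if n > 1 else 0.0
        return float(np.mean(runs) * dt)

    return FlipSummary(states=states, flip_fraction=flip_fraction,
                       first_flip_time=first_flip,
                       mean_dwell_crys=mean_dwell(0), mean_dwell_flip=mean_dwell(1))


def angle_distribution(
    angles: np.ndarray,
    bandwidth: float = 10.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Wrapped (circular) Gaussian kernel density on (−180, 180].

    Each sample contributes a Gaussian evaluated at the minimum angular
    image; the result integrates to 1 over the circle (in degrees⁻¹ units).
    Returns (grid degrees, density)."""
    angles = wrap_angle(np.asarray(angles, dtype=float))
    if angles.size < 2:
        raise ValueError("need at least 2 samples")
    if grid is None:
        grid = np.linspace(-180.0, 180.0, 361)
    d = wrap_angle(grid[:, None] - angles[None, :])
    dens = np.exp(-d ** 2 / (2 * bandwidth ** 2)).sum(axis=1)
    dens /= angles.size * bandwidth * np.sqrt(2 * np.pi)
    # renormalize for the (small) mass wrapped beyond one period
    dens /= np.trapezoid(dens, grid) if hasattr(np, "trapezoid") else np.trapz(dens, grid)
    return grid, dens


def helix_vector(coords: np.ndarray, system: ParticleSystem, chain: str,
                 first_resid: int = 315, last_resid: int = 333) -> np.ndarray:
    """M4 orientation vector: from Cα of the first residue to the geometric
    centre of the Cα atoms of residues first..last inclusive."""
    names = system.atom_names.astype(str)
    chains = system.chain_ids.astype(str)
    sel_range = (chains == chain) & (names == "CA") & \
        (system.residue_ids >= first_resid) & (system.residue_ids <= last_resid)
    idx = np.flatnonzero(sel_range)
    if idx.size == 0:
        raise ValueError(f"no Cα atoms for {chain}:{first_resid}-{last_resid}")
    start = np.flatnonzero((chains == chain) & (names == "CA") &
                           (system.residue_ids == first_resid))
    if start.size != 1:
        raise ValueError(f"no unique Cα for anchor residue {chain}:{first_resid}")
    center = coords[idx].mean(axis=0)
    return center - coords[int(start[0])]


def m4_theta(
    trajectory: Trajectory,
    chain: str,
    reference_coords: np.ndarray,
    reference_system: ParticleSystem | None = None,
    first_resid: int = 315,
    last_resid: int = 333,
) -> HelixOrientation:
    """θ(t): angle between the per-frame M4 vector and the reference
    structure's vector, in [0°, 180°].  θ is unsigned; compare against both
    up- and down-state reference vectors to annotate direction."""
    ref_sys = reference_system if reference_system is not None else trajectory.system
    v_ref = helix_vector(reference_coords, ref_sys, chain, first_resid, last_resid)
    v_ref = v_ref / np.linalg.norm(v_ref)
    theta = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        v = helix_vector(trajectory.coords[f], trajectory.system, chain,
                         first_resid, last_resid)
        c = np.dot(v / np.linalg.norm(v), v_ref)
        theta[f] = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return HelixOrientation(times=trajectory.times.copy(), theta=theta,
                            reference_vector=v_ref)
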