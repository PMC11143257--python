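"""Synthetic data generators with planted ground truth.

Every generator is a pure function of its seed: identical arguments give
bit-identical output.  The planted truth (event times, state labels, contact
probabilities, the underlying free-energy surface, the IC50) is always
returned alongside the data so analysis results can be checked against it;
no analysis module ever reads the truth.

The ion-channel generator emulates the statistical structure of voltage-driven
permeation runs: bulk ions diffuse but never fully traverse the pore, while a
Poisson-planted set of ions is driven monotonically through the selectivity
filter, one full traversal per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import HillsLog, ParticleSystem, Trajectory

__all__ = [
    "SyntheticSpec",
    "KBT_300K",
    "gen_ion_channel_traj",
    "gen_dihedral_series",
    "gen_distance_series",
    "gen_hills",
    "gen_dose_response",
    "make_channel_system",
]

#: kB·T at the simulation temperature of 300 K, kJ/mol.
KBT_300K = 2.494

#: Reported axial position of the SF backbone centre of mass (Å); the raw
#: pore-frame coordinate 0 maps to this value on the reported axis.
SF_AXIAL_OFFSET = 7.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Rates are per µs, durations and dt in ns, lengths in Å.  Defaults mirror
    a single 1 µs permeation run at desk scale: a 5 events/µs conductive
    channel, a cylindrical pore gate of 8 Å radius, and a selectivity filter
    spanning ±5 Å about its centre.
    """

    seed: int = 0
    duration: float = 1000.0          # ns
    dt: float = 0.5                   # ns per frame
    pore_radius: float = 8.0          # Å
    pore_half_length: float = 5.0     # Å
    permeation_rate: float = 5.0      # events / µs
    n_bulk_ions: int = 12
    flip_rate: float = 5.0            # flips / µs
    contact_p: float = 0.8
    fes_definition: list = field(default_factory=lambda: [
        # (center (rad, rad), depth kJ/mol, width rad) — double well in the
        # first torsion, matching a conductive/flipped two-basin landscape.
        ((-1.0, 0.0), 24.0, 0.45),
        ((1.8, 0.0), 20.0, 0.45),
    ])

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for name in ("permeation_rate", "flip_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.contact_p <= 1.0:
            raise ValueError("contact_p must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt))


# ---------------------------------------------------------------------------
# Pseudo-channel topology
# ---------------------------------------------------------------------------

def make_channel_system(n_ions: int, n_sf_ring: int = 8) -> ParticleSystem:
    """A minimal dimeric pseudo-channel: two chains of backbone-named SF atoms
    arranged in a ring (so their centre of mass sits on the pore axis), plus
    ``n_ions`` potassium ions."""
    atom_names, resnames, resids, chains, elements, masses = [], [], [], [], [], []
    for k in range(n_sf_ring):
        chain = "A" if k < n_sf_ring // 2 else "B"
        atom_names += ["N", "CA", "C", "O"]
        resnames += ["GLY"] * 4
        resids += [100 + k] * 4
        chains += [chain] * 4
        elements += ["N", "C", "C", "O"]
        masses += [14.007, 12.011, 12.011, 15.999]
    for i in range(n_ions):
        atom_names.append("K")
        resnames.append("K")
        resids.append(500 + i)
        chains.append("I")
        elements.append("K")
        masses.append(39.0983)
    return ParticleSystem(
        atom_names=np.array(atom_names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.array(resids),
        chain_ids=np.array(chains, dtype=object),
        elements=np.array(elements, dtype=object),
        masses=np.array(masses),
    )


def gen_ion_channel_traj(spec: SyntheticSpec) -> tuple[Trajectory, np.ndarray]:
    """Generate a pore-permeation trajectory with Poisson-planted traversals.

    Geometry (raw coordinates, Å): the box is 60×60×80 with the SF backbone
    centre at (30, 30, 40); the pore axis is z.  On the *reported* axis the SF
    centre sits at +7 Å, so the filter spans [7−L, 7+L] with L the pore half
    length and the default detection planes are that extent ±3 Å.

    Populations:

    * traversal ions — one per planted event, parked on the axis below the
      lower plane, then driven monotonically to above the upper plane over
      ``n_cross`` frames around the event time (crossing spans ≥ 5 frames so
      detection is never resolution-limited);
    * teaser ions — on-axis reflected Brownian motion confined below the
      lower plane (boundary recrossings, never a traversal);
    * bulk ions — reflected Brownian motion in z at radial distance > pore
      radius (full z excursions, but outside the cylindrical gate).

    Returns the trajectory and the planted event times (ns, sorted).
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    box = np.array([60.0, 60.0, 80.0])
    sf_center = np.array([30.0, 30.0, 40.0])
    L = spec.pore_half_length
    lower_rep = SF_AXIAL_OFFSET - L - 3.0    # reported-axis detection planes
    upper_rep = SF_AXIAL_OFFSET + L + 3.0
    lower_raw = lower_rep - SF_AXIAL_OFFSET  # raw z relative to SF centre
    upper_raw = upper_rep - SF_AXIAL_OFFSET

    n_cross = 12                       # frames per traversal
    if n_cross * spec.dt > spec.duration:
        raise ValueError("duration too short to resolve a single traversal")

    # Poisson-planted event times (event time = traversal midpoint).  Each
    # event gets its own ion, so events may interleave freely; the generator
    # only refuses rates beyond the frame resolution (more than one expected
    # event per frame interval).
    if spec.permeation_rate * spec.dt / 1000.0 >= 1.0:
        raise ValueError(
            "permeation rate too high: more than one expected event per frame"
        )
    lam = spec.permeation_rate * spec.duration / 1000.0
    n_events = int(rng.poisson(lam))
    margin = (n_cross / 2 + 1) * spec.dt
    event_times = np.sort(rng.uniform(margin, spec.duration - margin, size=n_events))

    n_teaser = 2
    n_ions = n_events + n_teaser + spec.n_bulk_ions
    system = make_channel_system(n_ions)
    n_sf_atoms = system.n_atoms - n_ions

    coords = np.zeros((n_frames, system.n_atoms, 3))
    times = np.arange(n_frames) * spec.dt + spec.dt

    # Static SF ring, radius 3 Å — centre of mass exactly on the axis.
    ring_angles = np.linspace(0, 2 * np.pi, n_sf_atoms // 4, endpoint=False)
    k = 0
    for ang in ring_angles:
        base = sf_center + np.array([3.0 * np.cos(ang), 3.0 * np.sin(ang), 0.0])
        for j in range(4):
            coords[:, k] = base + np.array([0.0, 0.0, 0.3 * j - 0.45])
            k += 1

    frame_idx = np.arange(n_frames)

    # Traversal ions.
    start_z = lower_raw - 3.0
    end_z = upper_raw + 3.0
    for e, t_ev in enumerate(event_times):
        i = n_sf_atoms + e
        mid = int(round(t_ev / spec.dt))
        f0 = mid - n_cross // 2
        z = np.full(n_frames, start_z)
        ramp = np.linspace(start_z, end_z, n_cross)
        for j in range(n_cross):
            fj = f0 + j
            if 0 <= fj < n_frames:
                z[fj] = ramp[j]
        z[frame_idx > f0 + n_cross - 1] = end_z
        coords[:, i, 0] = sf_center[0]
        coords[:, i, 1] = sf_center[1]
        coords[:, i, 2] = sf_center[2] + z

    # Teaser ions: reflected Brownian below the lower plane, on axis.
    step_sd = 0.8  # Å per frame
    for t in range(n_teaser):
        i = n_sf_atoms + n_events + t
        z = np.empty(n_frames)
        z[0] = lower_raw - 2.0
        steps = rng.normal(0.0, step_sd, size=n_frames - 1)
        hi = lower_raw + 1.5   # may poke just across the lower plane
        lo = lower_raw - 8.0
        for f in range(1, n_frames):
            znew = z[f - 1] + steps[f - 1]
            if znew > hi:
                znew = 2 * hi - znew
            if znew < lo:
                znew = 2 * lo - znew
            z[f] = np.clip(znew, lo, hi)
        coords[:, i, 0] = sf_center[0] + 0.5 * (t + 1)
        coords[:, i, 1] = sf_center[1]
        coords[:, i, 2] = sf_center[2] + z

    # Bulk ions: radially outside the gate, free reflected motion in z.
    for b in range(spec.n_bulk_ions):
        i = n_sf_atoms + n_events + n_teaser + b
        r = spec.pore_radius + 6.0 + 8.0 * rng.random()
        ang = rng.uniform(0, 2 * np.pi)
        z = np.empty(n_frames)
        z[0] = rng.uniform(-30.0, 30.0)
        steps = rng.normal(0.0, step_sd, size=n_frames - 1)
        for f in range(1, n_frames):
            znew = z[f - 1] + steps[f - 1]
            if znew > 35.0:
                znew = 70.0 - znew
            if znew < -35.0:
                znew = -70.0 - znew
            z[f] = np.clip(znew, -35.0, 35.0)
        coords[:, i, 0] = sf_center[0] + r * np.cos(ang)
        coords[:, i, 1] = sf_center[1] + r * np.sin(ang)
        coords[:, i, 2] = sf_center[2] + z

    boxes = np.tile(box, (n_frames, 1))
    traj = Trajectory(system=system, times=times, coords=coords, boxes=boxes)
    return traj, event_times


def wrap_angle(a):
    """Wrap angle(s) in degrees onto (−180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w if w.ndim else float(w)


def gen_dihedral_series(
    spec: SyntheticSpec,
    state_means: tuple[float, float] = (-40.0, 140.0),
    noise_sd: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-state telegraph ψ series with wrapped Gaussian noise.

    Dwell times in each state are Exponential(1/flip_rate); state 0 is the
    crystallographic orientation, state 1 the flipped one.  Requires the
    means to be separated by more than 4·noise_sd so states are resolvable.

    Returns (times ns, psi degrees in (−180, 180], state labels {0, 1}).
    """
    if abs(wrap_angle(state_means[1] - state_means[0])) <= 4 * noise_sd:
        raise ValueError("state means closer than 4 noise SDs; states unresolvable")
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_frames
    times = np.arange(n) * spec.dt + spec.dt
    labels = np.zeros(n, dtype=int)
    if spec.flip_rate > 0:
        mean_dwell = 1000.0 / spec.flip_rate  # ns
        t, state = 0.0, 0
        switch_times = []
        while t < spec.duration:
            t += rng.exponential(mean_dwell)
            switch_times.append(t)
        state_of_time = np.searchsorted(switch_times, times) % 2
        labels = state_of_time.astype(int)
    psi = np.where(labels == 0, state_means[0], state_means[1]) + \
        rng.normal(0.0, noise_sd, size=n)
    return times, wrap_angle(psi), labels


def gen_distance_series(
    spec: SyntheticSpec,
    contact_distance: float = 4.0,
    far_distance: float = 9.0,
    n_frames: int | None = None,
) -> tuple[np.ndarray, float]:
    """Per-frame residue-pair distances from i.i.d. Bernoulli(contact_p)
    contact states, with Gaussian jitter that never crosses the 5 Å contact
    cutoff.  Returns (distances Å, realized contact frequency)."""
    if not contact_distance < 5.0 < far_distance:
        raise ValueError("need contact_distance < 5 Å < far_distance")
    rng = np.random.default_rng(spec.seed + 2)
    n = n_frames if n_frames is not None else spec.n_frames
    states = rng.random(n) < spec.contact_p
    jitter_c = min(0.3, (5.0 - contact_distance) / 4.0)
    jitter_f = min(0.3, (far_distance - 5.0) / 4.0)
    d = np.where(states, contact_distance + rng.normal(0, jitter_c, n),
                 far_distance + rng.normal(0, jitter_f, n))
    d = np.where(states, np.minimum(d, 4.99), np.maximum(d, 5.01))
    return d, float(states.mean())


# ---------------------------------------------------------------------------
# Well-tempered metadynamics hills
# ---------------------------------------------------------------------------

def _true_fes_on_grid(fes_definition, grid_x, grid_y, period=2 * np.pi):
    """Evaluate the planted Gaussian-well surface on a periodic grid (kJ/mol,
    min-shifted to 0)."""
    X, Y = np.meshgrid(grid_x, grid_y, indexing="ij")
    V = np.zeros_like(X)
    for (cx, cy), depth, width in fes_definition:
        dx = _pwrap(X - cx, period)
        dy = _pwrap(Y - cy, period)
        V -= depth * np.exp(-(dx ** 2 + dy ** 2) / (2 * width ** 2))
    return V - V.min()


def _pwrap(d, period):
    return d - period * np.round(d / period)


def gen_hills(
    spec: SyntheticSpec,
    n_hills: int,
    h0: float = 1.2,
    sigma: float = 0.25,
    bias_factor: float = 8.0,
    n_grid: int = 73,
    mc_steps_per_hill: int = 25,
    kbt: float = KBT_300K,
) -> tuple[HillsLog, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate well-tempered metadynamics on the planted torsion surface.

    Hill centres follow a Metropolis walk on V_true + V_bias at kB·T; the
    deposited height obeys the well-tempered rule
    h_i = h0·exp(−V_bias(s_i) / ((γ−1)·kB·T)), and the running bias is kept
    on the same periodic grid later used for reconstruction.  CVs are torsions
    in radians on (−π, π]; the default h0/σ/γ match a 1.2 kJ/mol, 0.25-wide,
    bias-factor-8 protocol at 300 K.

    Returns (HillsLog, grid_x, grid_y, ground-truth FES on the grid).
    """
    if bias_factor <= 1:
        raise ValueError("bias factor must be > 1")
    if not spec.fes_definition:
        raise ValueError("fes_definition must be non-empty")
    rng = np.random.default_rng(spec.seed + 3)
    period = 2 * np.pi
    grid_x = np.linspace(-np.pi, np.pi, n_grid)
    grid_y = np.linspace(-np.pi, np.pi, n_grid)
    V_true = _true_fes_on_grid(spec.fes_definition, grid_x, grid_y, period)
    bias = np.zeros_like(V_true)

    def grid_index(s):
        ix = int(np.argmin(np.abs(_pwrap(grid_x - s[0], period))))
        iy = int(np.argmin(np.abs(_pwrap(grid_y - s[1], period))))
        return ix, iy

    def energy(s):
        ix, iy = grid_index(s)
        return V_true[ix, iy] + bias[ix, iy]

    # start in the deepest well
    start = min(spec.fes_definition, key=lambda w: -w[1])[0]
    s = np.array(start, dtype=float)
    e_s = energy(s)
    step_sd = 0.18
    centers = np.empty((n_hills, 2))
    heights = np.empty(n_hills)
    times = (np.arange(n_hills) + 1) * 0.5e-3  # one hill / 0.5 ps, in ns

    for i in range(n_hills):
        for _ in range(mc_steps_per_hill):
            prop = _pwrap(s + rng.normal(0, step_sd, 2), period)
            e_p = energy(prop)
            if e_p <= e_s or rng.random() < np.exp(-(e_p - e_s) / kbt):
                s, e_s = prop, e_p
        ix, iy = grid_index(s)
        h = h0 * np.exp(-bias[ix, iy] / ((bias_factor - 1.0) * kbt))
        centers[i] = s
        heights[i] = h
        gx = np.exp(-_pwrap(grid_x - s[0], period) ** 2 / (2 * sigma ** 2))
        gy = np.exp(-_pwrap(grid_y - s[1], period) ** 2 / (2 * sigma ** 2))
        bias += h * np.outer(gx, gy)
        e_s = V_true[grid_index(s)] + bias[grid_index(s)]

    log = HillsLog(times=times, centers=centers,
                   sigmas=np.full((n_hills, 2), sigma), heights=heights,
                   bias_factor=bias_factor)
    return log, grid_x, grid_y, V_true


def gen_dose_response(
    ic50: float,
    hill_coefficient: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> "pd.DataFrame":
    """Dose–response table from an exact Hill inhibition curve plus Gaussian
    noise, truncated to [0, 100] %.  Columns: dose_uM, pct_inhibition."""
    import pandas as pd

    x = np.asarray(concentrations, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    inh = 100.0 / (1.0 + (ic50 / x) ** hill_coefficient)
    if noise_sd > 0:
        inh = inh + rng.normal(0.0, noise_sd, size=x.shape)
    inh = np.clip(inh, 0.0, 100.0)
    return pd.DataFrame({"dose_uM": x, "pct_inhibition": inh})
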