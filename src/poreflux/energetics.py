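"""Free-energy surfaces from well-tempered metadynamics hills, basin
detection, and adiabatic-bias MD force bookkeeping.

Reconstruction follows the well-tempered estimator: the accumulated bias
V(s) = Σ_i h_i·G_i(s) (hill heights as deposited, i.e. already scaled by the
well-tempered rule) gives F(s) = −γ/(γ−1)·V(s), shifted so min F = 0.
Torsional collective variables are periodic; Gaussians are evaluated at the
minimum angular image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HillsLog

__all__ = [
    "FreeEnergySurface",
    "Basin",
    "AbmdRecord",
    "reconstruct_fes",
    "find_basins",
    "abmd_force",
]

CONTOUR_STEP = 4.0   # kJ/mol
CONTOUR_CAP = 80.0   # kJ/mol


def _pwrap(d, period):
    return d - period * np.round(d / period)


@dataclass
class Basin:
    location: tuple      # (cv1, cv2) at the basin minimum
    f_min: float         # kJ/mol (on the min-shifted surface)
    persistence: float   # depth below the lowest connecting saddle


@dataclass
class FreeEnergySurface:
    grid_x: np.ndarray
    grid_y: np.ndarray
    F: np.ndarray                # (nx, ny), kJ/mol, min-shifted to 0
    period: float
    contour_step: float = CONTOUR_STEP
    contour_cap: float = CONTOUR_CAP

    @property
    def grid_x_deg(self) -> np.ndarray:
        return np.degrees(self.grid_x)

    @property
    def grid_y_deg(self) -> np.ndarray:
        return np.degrees(self.grid_y)


@dataclass
class AbmdRecord:
    times: np.ndarray        # ns
    rho: np.ndarray          # nm
    rho_best: np.ndarray     # running extremum toward the target, nm
    force: np.ndarray        # kJ/mol/nm, instantaneous magnitude
    k: float                 # kJ/mol/nm²
    target: float            # nm
    total_force_abs: float   # Σ|F|
    total_force_sq: float    # Σ F² (the "square force" total)


def reconstruct_fes(
    hills: HillsLog,
    n_grid: int = 73,
    period: float = 2 * np.pi,
    grid_x: np.ndarray | None = None,
    grid_y: np.ndarray | None = None,
) -> FreeEnergySurface:
    """Sum the deposited Gaussians on a periodic grid and scale to F(s).

    An empty log yields a flat F = 0 surface.  The default grid spans one
    torsional period (−π, π] at 5° resolution.
    """
    if grid_x is None:
        grid_x = np.linspace(-period / 2, period / 2, n_grid)
    if grid_y is None:
        grid_y = np.linspace(-period / 2, period / 2, n_grid)
    V = np.zeros((len(grid_x), len(grid_y)))
    for i in range(hills.n_hills):
        cx, cy = hills.centers[i]
        sx, sy = hills.sigmas[i]
        gx = np.exp(-_pwrap(grid_x - cx, period) ** 2 / (2 * sx ** 2))
        gy = np.exp(-_pwrap(grid_y - cy, period) ** 2 / (2 * sy ** 2))
        V += hills.heights[i] * np.outer(gx, gy)
    g = hills.bias_factor
    F = -(g / (g - 1.0)) * V
    F -= F.min()
    return FreeEnergySurface(grid_x=np.asarray(grid_x), grid_y=np.asarray(grid_y),
                             F=F, period=period)


def find_basins(fes: FreeEnergySurface, min_depth: float = CONTOUR_STEP) -> list[Basin]:
    """Local minima on the periodic grid deeper than ``min_depth`` below
    their lowest connecting saddle.

    Implemented as a watershed-by-flooding (topological persistence): grid
    cells are visited in order of increasing F; a cell joins the basin of a
    lower neighbour, and when two basins first meet, the shallower one is
    merged unless its depth below the meeting level reaches ``min_depth``.
    """
    F = fes.F
    if not np.all(np.isfinite(F)):
        raise ValueError("FES must be finite")
    nx_, ny_ = F.shape
    order = np.argsort(F, axis=None)
    label = -np.ones(F.size, dtype=int)
    basin_min: list[float] = []
    basin_argmin: list[int] = []
    parent: list[int] = []
    persistence: dict[int, float] = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def neighbors(flat):
        i, j = divmod(flat, ny_)
        yield ((i + 1) % nx_) * ny_ + j
        yield ((i - 1) % nx_) * ny_ + j
        yield i * ny_ + (j + 1) % ny_
        yield i * ny_ + (j - 1) % ny_

    for flat in order:
        f_here = F.flat[flat]
        nb_basins = sorted({find(label[nb]) for nb in neighbors(flat) if label[nb] >= 0})
        if not nb_basins:
            label[flat] = len(parent)
            parent.append(len(parent))
            basin_min.append(f_here)
            basin_argmin.append(flat)
            continue
        # attach to the deepest adjacent basin, then merge the others into it
        deepest = min(nb_basins, key=lambda b: basin_min[b])
        label[flat] = deepest
        for b in nb_basins:
            if b == deepest:
                continue
            depth = f_here - basin_min[b]
            if depth >= min_depth and b not in persistence:
                persistence[b] = depth
            parent[b] = deepest
    roots = {find(b) for b in range(len(parent))}
    out = []
    for b in range(len(parent)):
        if b in roots:
            pers = float(F.max() - basin_min[b])
        elif b in persistence:
            pers = float(persistence[b])
        else:
            continue
        if pers < min_depth:
            continue
        i, j = divmod(basin_argmin[b], ny_)
        out.append(Basin(location=(float(fes.grid_x[i]), float(fes.grid_y[j])),
                         f_min=float(basin_min[b]), persistence=pers))
    out.sort(key=lambda b: b.f_min)
    return out


def abmd_force(
    times: np.ndarray,
    rho: np.ndarray,
    k: float = 5000.0,
    target: float = 0.5,
) -> AbmdRecord:
    """Ratchet-style adiabatic-bias force bookkeeping along a collective
    variable.

    The bias never pushes while the system progresses toward the target: the
    running best value ρ_best is the extremum reached toward the target
    (capped at it), and whenever ρ retreats from ρ_best the harmonic spring
    exerts |F| = k·|ρ − ρ_best|.  Both Σ|F| and Σ F² trajectory totals are
    reported.
    """
    times = np.asarray(times, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("collective-variable series must be finite")
    toward_smaller = rho[0] > target
    if toward_smaller:
        rho_best = np.maximum.accumulate(-rho)
        rho_best = np.maximum(-rho_best, target)  # running min, capped below at target
        retreat = rho - rho_best
    else:
        rho_best = np.minimum(np.maximum.accumulate(rho), target)
        retreat = rho_best - rho
    force = k * np.maximum(retreat, 0.0)
    return AbmdRecord(times=times, rho=rho, rho_best=rho_best, force=force,
                      k=k, target=target,
                      total_force_abs=float(force.sum()),
                      total_force_sq=float((force ** 2).sum()))
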