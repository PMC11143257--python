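"""Structure, trajectory and hills I/O plus atom selection.

Unit conventions used throughout the package: coordinates in Å, time in ns,
energies in kJ/mol.  Converters are applied at parse time (GRO nm → Å, hills
ps → ns).  Atom indices are 0-based internally; residue IDs keep the 1-based
numbering of the source topology verbatim.

File parsing is delegated to MDAnalysis; the in-memory containers below are
plain NumPy-backed dataclasses so that synthetic systems can be built and
analysed without ever touching a file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ParticleSystem",
    "Trajectory",
    "HillsLog",
    "FormatError",
    "SelectionError",
    "load_system",
    "iterate_frames",
    "load_trajectory",
    "write_trajectory",
    "select",
    "read_hills",
    "write_hills",
]

# Average isotopic masses (amu) for the elements that occur in channel/ion
# systems; used when the topology does not carry masses.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "K": 39.0983, "NA": 22.990, "CL": 35.45, "MG": 24.305,
    "CA": 40.078, "F": 18.998, "": 0.0,
}


class FormatError(ValueError):
    """Raised when a structure/trajectory/hills file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection expression cannot be parsed."""


@dataclass
class ParticleSystem:
    """Topology of a particle system: names, residues, chains, masses.

    Invariants: ``atom_index`` is the dense 0..n-1 position in each array;
    every atom belongs to exactly one (chain_id, residue_id).
    """

    atom_names: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("residue_names", "residue_ids", "chain_ids", "elements", "masses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != {n} atoms")
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_chains(self) -> int:
        return len(set(self.chain_ids.tolist()))

    def residue_key(self, i: int) -> tuple[str, int, str]:
        """(chain, resid, resname) of atom i."""
        return (str(self.chain_ids[i]), int(self.residue_ids[i]), str(self.residue_names[i]))


@dataclass
class Trajectory:
    """An in-memory trajectory: times (ns), coords (n_frames, n_atoms, 3) Å,
    and orthorhombic box lengths (n_frames, 3) Å."""

    system: ParticleSystem
    times: np.ndarray
    coords: np.ndarray
    boxes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"coords carry {self.coords.shape[1]} atoms but system has "
                f"{self.system.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def total_time_ns(self) -> float:
        """Simulated span covered by the frames (one frame interval per frame)."""
        if self.n_frames < 2:
            return 0.0
        dt = (self.times[-1] - self.times[0]) / (self.n_frames - 1)
        return float(dt * self.n_frames)


@dataclass
class HillsLog:
    """A well-tempered metadynamics hills log over two collective variables.

    times in ns, centers/sigmas in CV units (radians for torsions), heights
    in kJ/mol.  ``bias_factor`` γ > 1 is constant across the log.
    """

    times: np.ndarray
    centers: np.ndarray      # (n, 2)
    sigmas: np.ndarray       # (n, 2)
    heights: np.ndarray      # (n,)
    bias_factor: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if np.any(self.heights < 0):
            raise ValueError("hill heights must be >= 0")
        if np.any(self.sigmas <= 0):
            raise ValueError("hill widths must be > 0")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must be > 1")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("hill times must be nondecreasing")

    @property
    def n_hills(self) -> int:
        return len(self.heights)


# ---------------------------------------------------------------------------
# Structure / trajectory I/O via MDAnalysis
# ---------------------------------------------------------------------------

def _mda():
    import MDAnalysis as mda
    return mda


def _system_from_universe(u) -> ParticleSystem:
    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype=object)
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    resids = np.array([a.resid for a in u.atoms], dtype=int)
    # Chain identity: chainID if the format carries one, else segid, else "A".
    chains = []
    for a in u.atoms:
        cid = getattr(a, "chainID", "") or ""
        if not cid:
            cid = (a.segid or "").strip()
        if cid in ("", "SYSTEM"):
            cid = ""
        chains.append(cid)
    if all(c == "" for c in chains):
        warnings.warn("no chain identifiers in topology; assigning single chain 'A'")
        chains = ["A"] * n
    else:
        chains = [c if c else "A" for c in chains]
    elements = []
    masses = np.zeros(n)
    have_mass = hasattr(u.atoms, "masses")
    for i, a in enumerate(u.atoms):
        el = (getattr(a, "element", "") or "").strip().upper()
        if not el:
            # first alphabetic character of the atom name is a serviceable guess
            alpha = [c for c in a.name if c.isalpha()]
            el = alpha[0].upper() if alpha else ""
            if a.name.strip().upper() in _ELEMENT_MASSES:
                el = a.name.strip().upper()
        elements.append(el)
        if have_mass:
            try:
                masses[i] = float(a.mass)
            except Exception:
                masses[i] = _ELEMENT_MASSES.get(el, 0.0)
        else:
            masses[i] = _ELEMENT_MASSES.get(el, 0.0)
    if have_mass and np.all(masses == 0):
        masses = np.array([_ELEMENT_MASSES.get(e, 0.0) for e in elements])
    return ParticleSystem(
        atom_names=names, residue_names=resnames, residue_ids=resids,
        chain_ids=np.array(chains, dtype=object), elements=np.array(elements, dtype=object),
        masses=masses,
    )


def load_system(structure_path: str) -> tuple[ParticleSystem, np.ndarray]:
    """Parse a PDB or GRO structure into a ParticleSystem and first-frame
    coordinates in Å (MDAnalysis already converts GRO nm → Å)."""
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(structure_path))
    except Exception as exc:  # re-raise with a format error naming the culprit
        raise FormatError(f"cannot parse structure file {structure_path!r}: {exc}") from exc
    system = _system_from_universe(u)
    coords = np.array(u.atoms.positions, dtype=float)
    return system, coords


def iterate_frames(
    trajectory_path: str,
    system: ParticleSystem,
    stride: int = 1,
    structure_path: str | None = None,
) -> Iterator[tuple[float, np.ndarray, np.ndarray]]:
    """Stream every ``stride``-th frame as (time_ns, coords Å, box Å).

    Memory use is one frame at a time regardless of trajectory length.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if structure_path is not None:
            u = mda.Universe(str(structure_path), str(trajectory_path))
        else:
            u = mda.Universe(str(trajectory_path))
    if len(u.atoms) != system.n_atoms:
        raise FormatError(
            f"trajectory has {len(u.atoms)} atoms but system has {system.n_atoms}"
        )
    for i, ts in enumerate(u.trajectory):
        if i % stride:
            continue
        box = np.array(ts.dimensions[:3], dtype=float)
        yield float(ts.time) / 1000.0, np.array(ts.positions, dtype=float), box


def load_trajectory(
    trajectory_path: str,
    system: ParticleSystem,
    stride: int = 1,
    structure_path: str | None = None,
) -> Trajectory:
    """Materialize a Trajectory from a file (times converted ps → ns)."""
    times, coords, boxes = [], [], []
    for t, x, b in iterate_frames(trajectory_path, system, stride, structure_path):
        times.append(t)
        coords.append(x)
        boxes.append(b)
    if not times:
        raise FormatError(f"no frames read from {trajectory_path!r}")
    return Trajectory(system=system, times=np.array(times),
                      coords=np.array(coords), boxes=np.array(boxes))


def write_trajectory(traj: Trajectory, structure_path: str, trajectory_path: str) -> None:
    """Write a Trajectory as a GRO structure plus an XTC/TRR/DCD coordinate file
    (format chosen by extension), so synthetic fixtures exercise the real parsers."""
    mda = _mda()
    n = traj.system.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", traj.system.atom_names.astype(str))
    u.add_TopologyAttr("resnames", traj.system.residue_names.astype(str))
    u.add_TopologyAttr("resids", traj.system.residue_ids)
    u.add_TopologyAttr("masses", traj.system.masses)
    u.atoms.positions = traj.coords[0]
    u.dimensions = [*traj.boxes[0], 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(structure_path))
        with mda.Writer(str(trajectory_path), n_atoms=n) as w:
            for k in range(traj.n_frames):
                u.atoms.positions = traj.coords[k]
                u.dimensions = [*traj.boxes[k], 90.0, 90.0, 90.0]
                u.trajectory.ts.time = traj.times[k] * 1000.0  # ns -> ps
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "not" factor | "(" expr ")" | primary
#   primary  := ("chain"|"name"|"resname") VALUE+ | "resid" (N | N-M)+ | "all"
#
# Multiple values after a keyword are an implicit union ("name CA CB").

_KEYWORDS = {"chain", "name", "resname", "resid", "and", "or", "not", "all", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], system: ParticleSystem):
        self.tokens = tokens
        self.pos = 0
        self.sys = system

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword needs at least one value")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.take()
        if tok == "all":
            return np.ones(self.sys.n_atoms, dtype=bool)
        if tok == "chain":
            vals = set(self._values())
            return np.isin(self.sys.chain_ids.astype(str), list(vals))
        if tok == "name":
            vals = set(self._values())
            return np.isin(self.sys.atom_names.astype(str), list(vals))
        if tok == "resname":
            vals = set(self._values())
            return np.isin(self.sys.residue_names.astype(str), list(vals))
        if tok == "resid":
            mask = np.zeros(self.sys.n_atoms, dtype=bool)
            for v in self._values():
                if "-" in v[1:]:
                    cut = v.index("-", 1)
                    lo_s, hi_s = v[:cut], v[cut + 1:]
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid range {v!r}") from exc
                    mask |= (self.sys.residue_ids >= lo) & (self.sys.residue_ids <= hi)
                else:
                    try:
                        rid = int(v)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid {v!r}") from exc
                    mask |= self.sys.residue_ids == rid
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(system: ParticleSystem, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning a sorted, duplicate-free
    0-based atom index array.  An empty result is returned (with a warning),
    never silently swallowed."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, system).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return idx


# ---------------------------------------------------------------------------
# Hills logs
# ---------------------------------------------------------------------------

_HILLS_COLUMNS = ["time", "cv1", "cv2", "sigma_cv1", "sigma_cv2", "height", "biasf"]


def read_hills(path: str) -> HillsLog:
    """Read a PLUMED-style HILLS table.

    Expected whitespace-delimited columns: time (ps), cv1, cv2, sigma1,
    sigma2, height (kJ/mol), biasfactor.  A ``#! FIELDS`` header fixes the
    column order when present; otherwise the positional convention applies.
    Times are converted ps → ns.
    """
    col_order = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if s.startswith("#!") and "FIELDS" in s:
                    fields = s.split()[2:]
                    col_order = {name: i for i, name in enumerate(fields)}
                continue
            parts = s.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"non-numeric field on line {lineno} of {path!r}") from exc
            rows.append(vals)
    if not rows:
        raise FormatError(f"no hills records in {path!r}")
    arr = np.array(rows)

    def col(name: str, pos: int) -> np.ndarray:
        if col_order is not None:
            for key, i in col_order.items():
                if key == name or key.startswith(name):
                    return arr[:, i]
        return arr[:, pos]

    times_ps = col("time", 0)
    centers = np.column_stack([arr[:, 1], arr[:, 2]]) if col_order is None else \
        np.column_stack([col("cv1", 1), col("cv2", 2)])
    sigmas = np.column_stack([col("sigma_cv1", 3), col("sigma_cv2", 4)])
    heights = col("height", 5)
    biasf = col("biasf", 6)
    bf = float(biasf[0])
    if not np.allclose(biasf, bf):
        raise FormatError("mixed bias factors in hills log")
    return HillsLog(times=times_ps / 1000.0, centers=centers, sigmas=sigmas,
                    heights=heights, bias_factor=bf)


def write_hills(log: HillsLog, path: str) -> None:
    """Write a HillsLog in the PLUMED HILLS layout (times back to ps)."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n")
        for i in range(log.n_hills):
            fh.write(
                f"{log.times[i] * 1000.0:.6f} "
                f"{log.centers[i, 0]:.9f} {log.centers[i, 1]:.9f} "
                f"{log.sigmas[i, 0]:.9f} {log.sigmas[i, 1]:.9f} "
                f"{log.heights[i]:.9f} {log.bias_factor:.3f}\n"
            )
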