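"""Residue–residue contact probabilities and state difference maps.

Contacts use the single representative side-chain heavy atom per residue
type (CZ of Arg, CG of His, NZ of Lys, …, CE2 of Trp) and a 5 Å
minimum-image distance cutoff; a pair is "in contact" in a frame when the
representative-atom distance is strictly below the cutoff.  Difference maps
subtract down-state from up-state contact probabilities and retain pairs
with |Δp| above a threshold (0.25 by default), classified inter- vs
intra-chain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ParticleSystem, Trajectory

__all__ = [
    "REPRESENTATIVE_ATOMS",
    "ContactRecord",
    "representative_atom",
    "representative_atom_indices",
    "contact_probability",
    "difference_map",
]

#: One side-chain heavy atom per standard residue type (Cα for glycine).
REPRESENTATIVE_ATOMS = {
    "ARG": "CZ", "HIS": "CG", "LYS": "NZ", "ASP": "CG", "GLU": "CD",
    "SER": "OG", "THR": "CB", "ASN": "CG", "GLN": "CD", "CYS": "SG",
    "GLY": "CA", "PRO": "CG", "ALA": "CB", "VAL": "CB", "ILE": "CB",
    "LEU": "CG", "MET": "CE", "PHE": "CZ", "TYR": "OH", "TRP": "CE2",
}

DEFAULT_CUTOFF = 5.0        # Å
DEFAULT_THRESHOLD = 0.25    # |Δp| retention threshold


@dataclass
class ContactRecord:
    pair: tuple      # ((chainA, residA), (chainB, residB)), canonically ordered
    p: float
    cutoff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("contact probability must be in [0, 1]")
        if self.pair != tuple(sorted(self.pair)):
            raise ValueError("pair must be canonically ordered")


def representative_atom(
    system: ParticleSystem,
    chain: str,
    resid: int,
    extension: dict | None = None,
) -> int:
    """Index of the representative heavy atom of one residue; raises for an
    unmapped residue type unless an extension table covers it."""
    sel = (system.chain_ids.astype(str) == chain) & (system.residue_ids == resid)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError(f"residue {chain}:{resid} not in system")
    resname = str(system.residue_names[idx[0]]).upper()
    table = dict(REPRESENTATIVE_ATOMS)
    if extension:
        table.update({k.upper(): v for k, v in extension.items()})
    if resname not in table:
        raise KeyError(f"no representative atom mapped for residue type {resname!r}")
    want = table[resname]
    hit = idx[system.atom_names.astype(str)[idx] == want]
    if hit.size == 0:
        raise ValueError(f"residue {chain}:{resid} ({resname}) has no atom {want!r}")
    return int(hit[0])


def representative_atom_indices(
    system: ParticleSystem,
    extension: dict | None = None,
) -> pd.DataFrame:
    """Representative atom per protein residue: columns chain, resid,
    resname, atom_index.  Residue types outside the table (ions, lipids,
    water) are skipped."""
    table = dict(REPRESENTATIVE_ATOMS)
    if extension:
        table.update({k.upper(): v for k, v in extension.items()})
    rows = []
    seen = set()
    for i in range(system.n_atoms):
        key = (str(system.chain_ids[i]), int(system.residue_ids[i]))
        if key in seen:
            continue
        resname = str(system.residue_names[i]).upper()
        if resname not in table:
            continue
        try:
            ai = representative_atom(system, key[0], key[1], extension)
        except ValueError:
            continue
        seen.add(key)
        rows.append({"chain": key[0], "resid": key[1], "resname": resname,
                     "atom_index": ai})
    return pd.DataFrame(rows)


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a - b
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=-1)


def contact_probability(
    trajectory: Trajectory,
    pairs=None,
    cutoff: float = DEFAULT_CUTOFF,
    min_resid_separation: int = 2,
    extension: dict | None = None,
) -> list[ContactRecord]:
    """Fraction of frames each residue pair is in contact (strict ``< cutoff``
    minimum-image distance between representative atoms).

    ``pairs`` is either None (all pairs of mapped residues, excluding
    same-chain pairs with |Δresid| < ``min_resid_separation``) or an explicit
    list of ((chain, resid), (chain, resid)).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    reps = representative_atom_indices(trajectory.system, extension)
    atom_of = {(r.chain, r.resid): r.atom_index for r in reps.itertuples()}
    if pairs is None:
        keys = sorted(atom_of)
        pairs = []
        for a, b in itertools.combinations(keys, 2):
            if a[0] == b[0] and abs(a[1] - b[1]) < min_resid_separation:
                continue
            pairs.append((a, b))
    else:
        pairs = [tuple(sorted((tuple(a), tuple(b)))) for a, b in pairs]

    idx_a = np.array([atom_of[a] for a, _ in pairs], dtype=int)
    idx_b = np.array([atom_of[b] for _, b in pairs], dtype=int)
    n_contact = np.zeros(len(pairs), dtype=int)
    for f in range(trajectory.n_frames):
        d = _min_image_dist(trajectory.coords[f, idx_a],
                            trajectory.coords[f, idx_b], trajectory.boxes[f])
        n_contact += d < cutoff
    return [
        ContactRecord(pair=tuple(sorted(pr)), p=float(c / trajectory.n_frames),
                      cutoff=cutoff)
        for pr, c in zip(pairs, n_contact)
    ]


def difference_map(
    up: list[ContactRecord],
    down: list[ContactRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Up-minus-down contact difference map.

    A pair absent from one state contributes p = 0 there.  Pairs with
    |Δp| strictly above ``threshold`` are retained, both signs kept and
    labelled; ``class`` is "inter" when the chains differ, else "intra".
    Columns: chain_a, resid_a, chain_b, resid_b, p_up, p_down, dp, class.
    """
    p_up = {r.pair: r.p for r in up}
    p_down = {r.pair: r.p for r in down}
    rows = []
    for pair in sorted(set(p_up) | set(p_down)):
        pu = p_up.get(pair, 0.0)
        pdn = p_down.get(pair, 0.0)
        dp = pu - pdn
        if abs(dp) <= threshold:
            continue
        (ca, ra), (cb, rb) = pair
        rows.append({"chain_a": ca, "resid_a": ra, "chain_b": cb, "resid_b": rb,
                     "p_up": pu, "p_down": pdn, "dp": dp,
                     "class": "inter" if ca != cb else "intra"})
    df = pd.DataFrame(rows, columns=["chain_a", "resid_a", "chain_b", "resid_b",
                                     "p_up", "p_down", "dp", "class"])
    return df
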