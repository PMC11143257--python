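"""Shared fixtures: small in-memory systems and text-format structure files,
all generated programmatically."""

import numpy as np
import pytest

from poreflux.io import ParticleSystem, Trajectory


def make_backbone_chain(chain: str, resids, spacing: float = 3.8,
                        origin=(0.0, 0.0, 0.0)) -> tuple[list, np.ndarray]:
    """Rows (name, resname, resid, chain, element, mass) and coordinates for a
    straight poly-glycine backbone (N, CA, C, O per residue)."""
    rows, coords = [], []
    ox, oy, oz = origin
    for k, rid in enumerate(resids):
        base = np.array([ox + k * spacing, oy, oz])
        for name, el, m, off in [
            ("N", "N", 14.007, (0.0, 0.0, 0.0)),
            ("CA", "C", 12.011, (1.2, 0.8, 0.0)),
            ("C", "C", 12.011, (2.4, 0.0, 0.0)),
            ("O", "O", 15.999, (2.4, -1.2, 0.0)),
        ]:
            rows.append((name, "GLY", rid, chain, el, m))
            coords.append(base + np.array(off))
    return rows, np.array(coords)


def system_from_rows(rows) -> ParticleSystem:
    return ParticleSystem(
        atom_names=np.array([r[0] for r in rows], dtype=object),
        residue_names=np.array([r[1] for r in rows], dtype=object),
        residue_ids=np.array([r[2] for r in rows]),
        chain_ids=np.array([r[3] for r in rows], dtype=object),
        elements=np.array([r[4] for r in rows], dtype=object),
        masses=np.array([r[5] for r in rows]),
    )


def static_trajectory(system, coords, n_frames=1, box=(100.0, 100.0, 100.0),
                      dt=1.0) -> Trajectory:
    c = np.repeat(coords[None], n_frames, axis=0)
    return Trajectory(system=system, times=(np.arange(n_frames) + 1) * dt,
                      coords=c, boxes=np.tile(np.asarray(box, float), (n_frames, 1)))


@pytest.fixture
def dimer_system():
    """Two chains (A, B) of residues 310-340, straight backbones."""
    rows_a, xa = make_backbone_chain("A", range(310, 341))
    rows_b, xb = make_backbone_chain("B", range(310, 341), origin=(0.0, 20.0, 0.0))
    return system_from_rows(rows_a + rows_b), np.vstack([xa, xb])


@pytest.fixture
def dimer_pdb(tmp_path, dimer_system):
    """The dimer written as a hand-formatted PDB file."""
    system, coords = dimer_system
    path = tmp_path / "dimer.pdb"
    lines = []
    serial = 1
    prev_chain = None
    for i in range(system.n_atoms):
        ch = str(system.chain_ids[i])
        if prev_chain is not None and ch != prev_chain:
            lines.append("TER")
        prev_chain = ch
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {serial:5d} {system.atom_names[i]:>4s} "
            f"{system.residue_names[i]:>3s} {ch}{system.residue_ids[i]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
            f"{system.elements[i]:>2s}"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
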