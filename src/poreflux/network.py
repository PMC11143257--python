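"""Protein structure network: correlation-filtered shortest communication
paths between residue groups (e.g. the proximal C-terminus and the
selectivity filter) and the metapath of most frequent edges.

Edges carry weight −log(contact probability) so that frequent contacts are
short, mapping interaction intensity onto an additive path cost; path
membership is restricted to residues whose Cα fluctuations correlate with a
path endpoint above a cutoff (0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ParticleSystem, Trajectory

__all__ = [
    "PSNGraph",
    "MetaPath",
    "superpose",
    "correlation_matrix",
    "build_graph",
    "shortest_paths",
]

DEFAULT_CORRELATION_CUTOFF = 0.8
DEFAULT_META_FRACTION = 0.2


@dataclass
class PSNGraph:
    graph: nx.Graph
    correlations: pd.DataFrame      # symmetric, residue-keyed
    correlation_cutoff: float


@dataclass
class MetaPath:
    nodes: list
    edges: list                     # [((a, b), frequency), ...]
    n_paths: int


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing RMSD of P onto Q (both centred)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid-body fit of every frame onto a reference coordinate set.

    coords: (n_frames, n_atoms, 3); reference: (n_atoms, 3).  Returns the
    superposed copy."""
    ref_c = reference - reference.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        X = coords[f] - coords[f].mean(axis=0)
        R = _kabsch(X, ref_c)
        out[f] = X @ R.T
    return out


def correlation_matrix(
    trajectory: Trajectory,
    selection: np.ndarray,
    reference: np.ndarray | None = None,
    fit: bool = True,
) -> pd.DataFrame:
    """Dynamic cross-correlation of Cα displacement vectors.

    Frames are first superposed on the reference (default: the first frame's
    selected atoms) unless ``fit=False``; then
    C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) with Δr = r − ⟨r⟩.  Note the fit
    absorbs rigid-body motion, so displacement shared by *all* selected atoms
    is removed by construction.  Zero-variance atoms are excluded with a
    warning.  Rows/columns are keyed by (chain, resid)."""
    import warnings

    selection = np.asarray(selection, dtype=int)
    X = trajectory.coords[:, selection, :]
    if fit:
        ref = reference if reference is not None else X[0]
        X = superpose(X, ref)
    dX = X - X.mean(axis=0, keepdims=True)
    # ⟨Δr_i·Δr_j⟩: sum over xyz of per-pair covariances
    n_frames, n_atoms, _ = dX.shape
    cov = np.einsum("fik,fjk->ij", dX, dX) / n_frames
    var = np.diag(cov).copy()
    keys = [(str(trajectory.system.chain_ids[i]), int(trajectory.system.residue_ids[i]))
            for i in selection]
    good = var > 1e-12
    if not good.all():
        bad = [keys[i] for i in np.flatnonzero(~good)]
        warnings.warn(f"excluding zero-variance atoms: {bad}")
    idx = np.flatnonzero(good)
    denom = np.sqrt(np.outer(var[idx], var[idx]))
    C = cov[np.ix_(idx, idx)] / denom
    kept = [keys[i] for i in idx]
    return pd.DataFrame(C, index=pd.MultiIndex.from_tuples(kept),
                        columns=pd.MultiIndex.from_tuples(kept))


def build_graph(
    contact_records,
    correlations: pd.DataFrame | None = None,
    correlation_cutoff: float = DEFAULT_CORRELATION_CUTOFF,
) -> PSNGraph:
    """Residue graph with edge weight −log p for every contact with p > 0."""
    g = nx.Graph()
    for rec in contact_records:
        if rec.p <= 0:
            continue
        a, b = rec.pair
        g.add_edge(a, b, weight=float(-np.log(rec.p)), p=rec.p)
    if correlations is None:
        correlations = pd.DataFrame()
    return PSNGraph(graph=g, correlations=correlations,
                    correlation_cutoff=correlation_cutoff)


def _node_eligible(psn: PSNGraph, node, endpoints) -> bool:
    """A node may sit on a path iff its fluctuation correlation to at least
    one endpoint of interest reaches the cutoff (endpoints always pass)."""
    if node in endpoints:
        return True
    if psn.correlations.empty:
        return True
    c = psn.correlations
    best = -np.inf
    for ep in endpoints:
        if node in c.index and ep in c.columns:
            best = max(best, float(c.loc[[node], [ep]].iloc[0, 0]))
    return best >= psn.correlation_cutoff


def shortest_paths(
    psn: PSNGraph,
    source_set,
    target_set,
    meta_fraction: float = DEFAULT_META_FRACTION,
) -> tuple[list, MetaPath]:
    """Dijkstra shortest path per (source, target) pair on the
    correlation-filtered graph; metapath = edges appearing in at least
    ``meta_fraction`` of retained paths, with their frequencies.

    Unreachable pairs and pairs whose subgraph excludes all routes simply
    contribute no path; an empty result is not an error."""
    source_set = [tuple(s) for s in source_set]
    target_set = [tuple(t) for t in target_set]
    retained = []
    for s in source_set:
        for t in target_set:
            if s == t or s not in psn.graph or t not in psn.graph:
                continue
            endpoints = {s, t}
            keep = [n for n in psn.graph.nodes if _node_eligible(psn, n, endpoints)]
            sub = psn.graph.subgraph(keep)
            try:
                path = nx.dijkstra_path(sub, s, t, weight="weight")
            except nx.NetworkXNoPath:
                continue
            cost = nx.path_weight(sub, path, weight="weight")
            retained.append({"source": s, "target": t, "path": path, "cost": cost})

    edge_count: dict = {}
    for r in retained:
        for a, b in zip(r["path"], r["path"][1:]):
            e = tuple(sorted((a, b)))
            edge_count[e] = edge_count.get(e, 0) + 1
    n_paths = len(retained)
    meta_edges = []
    if n_paths:
        for e, c in sorted(edge_count.items(), key=lambda kv: -kv[1]):
            freq = c / n_paths
            if freq >= meta_fraction:
                meta_edges.append((e, freq))
    # nodes ordered by first appearance along retained paths
    seen, nodes = set(), []
    meta_node_set = {n for e, _ in meta_edges for n in e}
    for r in retained:
        for n in r["path"]:
            if n in meta_node_set and n not in seen:
                seen.add(n)
                nodes.append(n)
    return retained, MetaPath(nodes=nodes, edges=meta_edges, n_paths=n_paths)
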