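"""Dynamic residue-interaction networks and communication pathways.

Residues are network nodes placed at the Cβ atom (Cα for glycine); an
edge joins two residues whenever their nodes are within 6.5 Å in a
frame.  Over a trajectory each pair gets an *occupancy* — the fraction
of frames in which it is in contact — and the consensus network keeps
the pairs at or above an occupancy threshold (default 0.5).  Successive
residues of a chain are always connected (backbone guarantee), so
coarse-grained chains never fragment.

On the unweighted consensus graph:

* betweenness centrality (BC) counts, for every residue, the shortest
  paths running through it, with fractional credit when a pair has
  several equally short paths — high-BC residues mediate network
  communication;
* communication pathways are all shortest (fewest-edge) source→sink
  paths, enumerated deterministically in lexicographic order from
  Floyd–Warshall all-pairs distances; steps whose endpoints lie in
  different chains are reported as inter-chain *bridges*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .structio import CoarseStructure, ResidueSelection, Trajectory

logger = logging.getLogger("allodyn.resnetwork")

__all__ = [
    "ResidueNetwork",
    "CommunicationPath",
    "build_network",
    "network_from_structure",
    "betweenness",
    "floyd_warshall",
    "shortest_paths",
    "compare_bc",
]

DEFAULT_CUTOFF = 6.5
DEFAULT_OCCUPANCY = 0.5


@dataclass
class CommunicationPath:
    """One shortest communication pathway, source → sink."""

    residues: list[str]
    n_edges: int
    bridges: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "residues": list(self.residues),
            "n_edges": self.n_edges,
            "bridges": [list(b) for b in self.bridges],
        }


@dataclass
class ResidueNetwork:
    """Consensus contact graph of a trajectory."""

    structure: CoarseStructure
    edge_occupancy: np.ndarray
    cutoff: float
    occupancy_threshold: float
    graph: nx.Graph = field(repr=False)
    trajectory: Trajectory | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.structure.n_residues

    def consensus_edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def node_index(self, residue: int | str) -> int:
        if isinstance(residue, str):
            return self.structure.index_of(residue)
        if not 0 <= residue < self.n_nodes:
            raise IndexError(f"residue index {residue} out of range")
        return int(residue)


def _node_frames(traj: Trajectory) -> np.ndarray:
    """Per-frame node coordinates: Cβ offsets ride rigidly on the Cα."""
    s = traj.structure_ref
    offset = np.where(
        s.has_cb[:, None], s.cb_coords - s.ca_coords, 0.0
    )
    return traj.frames + offset[None, :, :]


def _backbone_pairs(structure: CoarseStructure) -> list[tuple[int, int]]:
    return [
        (i, i + 1)
        for i in range(structure.n_residues - 1)
        if structure.residues[i].chain_id == structure.residues[i + 1].chain_id
    ]


def build_network(
    traj: Trajectory,
    structure: CoarseStructure | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    occupancy_threshold: float = DEFAULT_OCCUPANCY,
    backbone_guarantee: bool = True,
) -> ResidueNetwork:
    """Consensus residue network of a trajectory.

    Contacts are evaluated per frame (no superposition needed: distances
    are frame-internal) on Cβ-else-Cα nodes; a consensus edge requires
    contact occupancy ≥ ``occupancy_threshold``.  With the backbone
    guarantee, successive residues of a chain are connected even when
    they fail the occupancy test (logged when that happens).
    """
    structure = structure if structure is not None else traj.structure_ref
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    nodes = _node_frames(traj)
    n = structure.n_residues
    occ = np.zeros((n, n))
    for f in range(traj.n_frames):
        occ += squareform(pdist(nodes[f]) <= cutoff).astype(float)
    occ /= traj.n_frames
    np.fill_diagonal(occ, 0.0)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(occ >= occupancy_threshold, 1))
    G.add_edges_from(zip(ii.tolist(), jj.tolist()))
    if backbone_guarantee:
        for i, j in _backbone_pairs(structure):
            if not G.has_edge(i, j):
                logger.info(
                    "backbone guarantee added edge %s-%s (occupancy %.2f)",
                    structure.labels[i], structure.labels[j], occ[i, j],
                )
                G.add_edge(i, j)
    return ResidueNetwork(structure, occ, cutoff, occupancy_threshold, G, traj)


def network_from_structure(
    structure: CoarseStructure,
    cutoff: float = DEFAULT_CUTOFF,
    occupancy_threshold: float = DEFAULT_OCCUPANCY,
    backbone_guarantee: bool = True,
) -> ResidueNetwork:
    """Static single-frame network of a structure (Cβ-else-Cα nodes)."""
    traj = Trajectory(structure.ca_coords[None, :, :], structure, aligned=True)
    return build_network(traj, structure, cutoff, occupancy_threshold,
                         backbone_guarantee)


def betweenness(network: ResidueNetwork, frame_average: bool = False) -> np.ndarray:
    """Unnormalised shortest-path betweenness per residue.

    Pairs with several equally short paths contribute fractionally.
    ``frame_average=True`` instead builds one graph per trajectory frame
    and averages the per-frame BC values (the consensus threshold is
    ignored in that variant).
    """
    if frame_average:
        if network.trajectory is None:
            raise ValueError("no trajectory stored: cannot frame-average BC")
        nodes = _node_frames(network.trajectory)
        total = np.zeros(network.n_nodes)
        for f in range(network.trajectory.n_frames):
            contact = squareform(pdist(nodes[f]) <= network.cutoff)
            G = nx.Graph()
            G.add_nodes_from(range(network.n_nodes))
            ii, jj = np.nonzero(np.triu(contact, 1))
            G.add_edges_from(zip(ii.tolist(), jj.tolist()))
            bc = nx.betweenness_centrality(G, normalized=False)
            total += np.array([bc[i] for i in range(network.n_nodes)])
        return total / network.trajectory.n_frames
    bc = nx.betweenness_centrality(network.graph, normalized=False)
    return np.array([bc[i] for i in range(network.n_nodes)])


def floyd_warshall(network: ResidueNetwork) -> np.ndarray:
    """All-pairs shortest-path distances (edge counts) on the consensus graph.

    Unreachable pairs are ``inf``.
    """
    n = network.n_nodes
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i, j in network.graph.edges:
        D[i, j] = D[j, i] = 1.0
    for k in range(n):
        np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


def shortest_paths(
    network: ResidueNetwork,
    source: int | str,
    sink: int | str,
    max_paths: int = 50,
) -> list[CommunicationPath]:
    """All minimum-length source→sink paths, lexicographically ordered.

    At most ``max_paths`` paths are returned.  An unreachable sink gives
    an empty list with a warning.
    """
    s = network.node_index(source)
    t = network.node_index(sink)
    if s == t:
        raise ValueError("source and sink must differ")
    D = floyd_warshall(network)
    if not np.isfinite(D[s, t]):
        logger.warning(
            "sink %s unreachable from source %s",
            network.structure.labels[t], network.structure.labels[s],
        )
        return []
    labels = network.structure.labels
    chains = network.structure.chain_ids
    adj = {u: sorted(network.graph.neighbors(u)) for u in network.graph.nodes}
    paths: list[list[int]] = []

    def extend(u: int, acc: list[int]) -> None:
        if len(paths) >= max_paths:
            return
        if u == t:
            paths.append(list(acc))
            return
        for v in adj[u]:
            if D[v, t] == D[u, t] - 1:
                acc.append(v)
                extend(v, acc)
                acc.pop()
                if len(paths) >= max_paths:
                    return

    extend(s, [s])
    out = []
    for p in paths:
        bridges = [
            (labels[a], labels[b])
            for a, b in zip(p[:-1], p[1:])
            if chains[a] != chains[b]
        ]
        out.append(CommunicationPath([labels[i] for i in p], len(p) - 1, bridges))
    return out


def compare_bc(
    network_a: ResidueNetwork,
    network_b: ResidueNetwork,
    selection: ResidueSelection,
    structure: CoarseStructure | None = None,
):
    """Per-site betweenness change between two networks.

    Sites are matched across networks by ``chain:resnum`` label (the two
    networks may index residues differently, e.g. a monomer versus the
    same chain inside a complex).  A label absent from one network is
    kept in the table and flagged missing rather than dropped.
    """
    import pandas as pd

    structure = structure if structure is not None else network_a.structure
    bc_a = betweenness(network_a)
    bc_b = betweenness(network_b)
    idx_a = {lab: i for i, lab in enumerate(network_a.structure.labels)}
    idx_b = {lab: i for i, lab in enumerate(network_b.structure.labels)}
    rows = []
    for i in selection.sorted():
        lab = structure.labels[i]
        a = bc_a[idx_a[lab]] if lab in idx_a else np.nan
        b = bc_b[idx_b[lab]] if lab in idx_b else np.nan
        rows.append({
            "site": lab,
            "bc_a": a,
            "bc_b": b,
            "delta_bc": b - a,
            "missing": lab not in idx_a or lab not in idx_b,
        })
    return pd.DataFrame(rows)
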