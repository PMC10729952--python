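"""Virtual C-beta reconstruction and residue graph construction.

Two graph modes are supported: the contact graph (``cgraph``), which connects
every residue pair whose virtual C-beta atoms lie within a distance cutoff
(default 12 A) and is symmetric by construction, and a k-nearest-neighbor
graph (``knn``, default k=30) with a fixed in-degree. Self-loops are removed
in both modes and masked residues are excluded entirely before any neighbor
selection.

Edges are directed and stored as parallel ``src``/``dst`` arrays; the edge
``(j, i)`` carries the message from residue j to residue i. For each edge the
second-order-edge (SOE) index enumerates the shared neighbors
``n in N_i and N_j`` through which two-hop edge compositions pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import VIRTUAL_CB_COEFF
from .structures import BackboneStructure


def virtual_cbeta(structure: BackboneStructure) -> np.ndarray:
    """Reconstruct a virtual C-beta position for every residue.

    With u = CA - N and v = C - CA, the virtual C-beta is the fixed linear
    combination ``a*u + b*v + c*(u x v) + CA`` with coefficients
    (-0.58273431, 0.56802827, -0.54067466). The formula uses backbone atoms
    only, so it is defined for every residue type including glycine.
    Rows for masked residues are NaN.
    """
    a, b, c = VIRTUAL_CB_COEFF
    u = structure.coords_CA - structure.coords_N
    v = structure.coords_C - structure.coords_CA
    cb = a * u + b * v + c * np.cross(u, v) + structure.coords_CA
    cb = np.where(structure.mask[:, None], cb, np.nan)
    return cb


@dataclass
class ContactGraph:
    """Directed residue graph with symmetric-pair and SOE indices."""

    n_nodes: int
    src: np.ndarray  # (E,) source residue j of each directed edge
    dst: np.ndarray  # (E,) target residue i
    distances: np.ndarray  # (E,) virtual C-beta distance of each edge
    mode: str  # "cgraph" | "knn"
    cutoff: float | None = None
    k: int | None = None
    #: reverse_index[e] = index of edge (dst[e], src[e]), or -1 if absent
    reverse_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    neighbors: list[np.ndarray] = field(default_factory=list)
    # flattened SOE triples: for row t, edge soe_edge[t] has shared neighbor
    # reachable via edges soe_in[t] (i->n) and soe_out[t] (n->j)
    soe_edge: np.ndarray = field(default=None)  # type: ignore[assignment]
    soe_in: np.ndarray = field(default=None)  # type: ignore[assignment]
    soe_out: np.ndarray = field(default=None)  # type: ignore[assignment]
    soe_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def shared_neighbors(self, edge_index: int) -> np.ndarray:
        """Sorted shared-neighbor node list of one edge (for inspection)."""
        rows = self.soe_edge == edge_index
        return np.sort(self.dst[self.soe_in[rows]])

    def to_tsv(self) -> str:
        lines = ["source\ttarget\tdistance"]
        for j, i, d in zip(self.src, self.dst, self.distances):
            lines.append(f"{j}\t{i}\t{d:.4f}")
        return "\n".join(lines) + "\n"


def _edge_lookup(src: np.ndarray, dst: np.ndarray) -> dict[tuple[int, int], int]:
    return {(int(j), int(i)): e for e, (j, i) in enumerate(zip(src, dst))}


def _finalize(graph: ContactGraph) -> ContactGraph:
    lookup = _edge_lookup(graph.src, graph.dst)
    graph.reverse_index = np.array(
        [lookup.get((int(i), int(j)), -1) for j, i in zip(graph.src, graph.dst)],
        dtype=int,
    )
    neighbors: list[np.ndarray] = [np.empty(0, dtype=int)] * graph.n_nodes
    by_dst: dict[int, list[int]] = {}
    for j, i in zip(graph.src, graph.dst):
        by_dst.setdefault(int(i), []).append(int(j))
    for i, lst in by_dst.items():
        neighbors[i] = np.array(sorted(lst), dtype=int)
    graph.neighbors = neighbors
    enumerate_soe(graph, lookup)
    return graph


def enumerate_soe(graph: ContactGraph,
                  lookup: dict[tuple[int, int], int] | None = None) -> None:
    """Fill the flattened second-order-edge index of ``graph`` in place.

    For each directed edge (i -> j) the shared neighbors are
    ``n in N_i and N_j`` (in-neighbor sets); each contributes the edge pair
    (i -> n) and (n -> j). In KNN mode a shared neighbor is skipped when
    either constituent directed edge is absent.
    """
    if lookup is None:
        lookup = _edge_lookup(graph.src, graph.dst)
    neighbor_sets = [set(map(int, lst)) for lst in graph.neighbors]
    soe_edge: list[int] = []
    soe_in: list[int] = []
    soe_out: list[int] = []
    counts = np.zeros(graph.n_edges, dtype=int)
    for e, (j, i) in enumerate(zip(graph.src, graph.dst)):
        i, j = int(i), int(j)
        shared = sorted(neighbor_sets[i] & neighbor_sets[j])
        for n in shared:
            e_in = lookup.get((j, n), -1)
            e_out = lookup.get((n, i), -1)
            if e_in < 0 or e_out < 0:
                continue
            soe_edge.append(e)
            soe_in.append(e_in)
            soe_out.append(e_out)
            counts[e] += 1
    graph.soe_edge = np.array(soe_edge, dtype=int)
    graph.soe_in = np.array(soe_in, dtype=int)
    graph.soe_out = np.array(soe_out, dtype=int)
    graph.soe_counts = counts


def build_cgraph(structure: BackboneStructure, cutoff: float = 12.0,
                 ) -> ContactGraph:
    """Contact graph: edges between unmasked pairs with virtual C-beta
    distance <= cutoff (boundary inclusive), both directions present."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cb = virtual_cbeta(structure)
    idx = np.flatnonzero(structure.mask)
    if idx.size == 0:
        raise ValueError("graph construction needs at least one unmasked residue")
    d = cdist(cb[idx], cb[idx])
    within = d <= cutoff
    np.fill_diagonal(within, False)
    a, b = np.nonzero(within)
    graph = ContactGraph(
        n_nodes=structure.length,
        src=idx[a], dst=idx[b], distances=d[a, b],
        mode="cgraph", cutoff=cutoff,
    )
    return _finalize(graph)


def build_knn(structure: BackboneStructure, k: int = 30) -> ContactGraph:
    """KNN graph: each unmasked residue receives edges from its k nearest
    unmasked residues (fewer when the chain is short). Ties in distance are
    broken toward the lower residue index for determinism."""
    if k <= 0:
        raise ValueError("k must be positive")
    cb = virtual_cbeta(structure)
    idx = np.flatnonzero(structure.mask)
    if idx.size == 0:
        raise ValueError("graph construction needs at least one unmasked residue")
    d = cdist(cb[idx], cb[idx])
    np.fill_diagonal(d, np.inf)
    src_list, dst_list, dist_list = [], [], []
    kk = min(k, idx.size - 1)
    for col in range(idx.size):
        order = np.lexsort((np.arange(idx.size), d[:, col]))[:kk]
        for row in order:
            src_list.append(idx[row])
            dst_list.append(idx[col])
            dist_list.append(d[row, col])
    graph = ContactGraph(
        n_nodes=structure.length,
        src=np.array(src_list, dtype=int),
        dst=np.array(dst_list, dtype=int),
        distances=np.array(dist_list, dtype=float),
        mode="knn", k=k,
    )
    return _finalize(graph)
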