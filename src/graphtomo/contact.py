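"""Distance-cutoff contact graphs.

A structure becomes an undirected, unweighted graph: one node per point
(alpha carbon or density centroid), and an edge wherever the Euclidean
distance between two points is strictly below the cutoff. Control graphs
come from atomic coordinates (cutoff in angstroms); observable graphs come
from density centroids (cutoff in pixels). At the default voxel size of
1 A/pixel the two cutoff scales coincide.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structures import CaStructure

#: Cutoff best suited to cross-chain interfaces of multimeric assemblies.
D_CUT_MULTIMER = 8.0
#: Cutoff best suited to long-range tertiary contacts of monomers.
D_CUT_MONOMER = 9.0


@dataclass
class ProteinGraph:
    """An undirected contact graph with its provenance.

    ``graph`` holds integer node ids ``0..n-1`` (insertion order of the
    source points); a node may carry a ``label`` attribute naming its
    residue. ``role`` is ``"control"`` for structure-derived graphs and
    ``"observable"`` for density-derived graphs; ``cutoff`` is in angstroms
    or pixels accordingly.
    """

    graph: nx.Graph
    role: str = "control"
    cutoff: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("control", "observable"):
            raise ValueError(f"unknown graph role {self.role!r}")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}


def graph_from_points(
    points: np.ndarray,
    cutoff: float,
    role: str = "control",
    source_id: str = "",
    labels: list[str] | None = None,
) -> ProteinGraph:
    """Build the contact graph of a 3-D point set.

    An edge joins points ``v`` and ``w`` iff ``d(v, w) < cutoff`` (strict
    inequality; a pair exactly at the cutoff is not connected). The k-d tree
    is only a candidate filter — membership is decided by an exact
    double-precision squared-distance comparison, so the edge set matches a
    brute-force scan.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")

    g = nx.Graph()
    for i in range(len(pts)):
        if labels is not None:
            g.add_node(i, label=labels[i])
        else:
            g.add_node(i)

    # query_pairs uses a closed ball; re-check squared distances to keep "<" strict
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(r=cutoff):
        d2 = float(np.dot(pts[i] - pts[j], pts[i] - pts[j]))
        if d2 < cutoff * cutoff:
            g.add_edge(int(i), int(j))
    return ProteinGraph(graph=g, role=role, cutoff=float(cutoff), source_id=source_id)


def build_contact_graph(structure: CaStructure, d_cut: float) -> ProteinGraph:
    """Control graph of an alpha-carbon trace at cutoff ``d_cut`` (angstrom)."""
    return graph_from_points(
        structure.coords,
        cutoff=d_cut,
        role="control",
        source_id=structure.source_id or structure.name,
        labels=structure.labels(),
    )
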