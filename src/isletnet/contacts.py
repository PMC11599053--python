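"""Nuclear-distance cell-contact graphs.

Two islet cells are considered to be in contact when their nuclei lie closer
than a threshold distance — 30 um by default, a surrogate for the reach of
delta-cell membrane projections observed in 3-D electron microscopy. The
comparison is strict (<): pairs at exactly the threshold are not contacts.

The headline connectivity metric is the fraction of delta-cells with at least
one beta-cell neighbour, the quantity whose decay under beta-cell loss is
simulated in :mod:`isletnet.ablation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import CELL_TYPES, IsletArchitecture

DEFAULT_THRESHOLD_UM = 30.0


@dataclass(frozen=True)
class ContactGraph:
    """Thresholded contact graph over the cells of one islet.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are cell
    ids carrying a ``cell_type`` attribute and whose edges carry
    ``distance_um``. Every cell of the source architecture appears as a node;
    isolated nodes are allowed.
    """

    islet_id: str
    threshold_um: float
    graph: nx.Graph

    @property
    def node_types(self) -> dict[int, str]:
        return dict(self.graph.nodes(data="cell_type"))

    def cells_of_type(self, cell_type: str) -> list[int]:
        if cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {cell_type!r}")
        return [
            n for n, t in self.graph.nodes(data="cell_type") if t == cell_type
        ]

    def edge_table(self) -> pd.DataFrame:
        """Edge list as a DataFrame (cell_id_a, cell_id_b, distance_um)."""
        rows = [
            (min(u, v), max(u, v), d)
            for u, v, d in self.graph.edges(data="distance_um")
        ]
        rows.sort()
        return pd.DataFrame(
            rows, columns=["cell_id_a", "cell_id_b", "distance_um"]
        )


def build_contact_graph(
    arch: IsletArchitecture, threshold_um: float = DEFAULT_THRESHOLD_UM
) -> ContactGraph:
    """Build the contact graph of an architecture.

    Candidate pairs come from a k-d tree range query; each is then re-checked
    with the exact Euclidean distance so the edge set equals the brute-force
    all-pairs computation with strict ``distance < threshold_um``.
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")
    if len(arch.cells) < 1:
        raise ValueError("architecture is empty")
    ids = arch.cells["cell_id"].to_numpy(int)
    types = arch.cells["cell_type"].to_numpy(str)
    pts = arch.positions
    g = nx.Graph()
    g.add_nodes_from(
        (int(i), {"cell_type": t}) for i, t in zip(ids, types)
    )
    if len(pts) > 1:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r=threshold_um, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
            keep = d < threshold_um  # strict: ties at the threshold excluded
            for (a, b), dist in zip(pairs[keep], d[keep]):
                g.add_edge(int(ids[a]), int(ids[b]), distance_um=float(dist))
    return ContactGraph(
        islet_id=arch.islet_id, threshold_um=float(threshold_um), graph=g
    )


def delta_beta_connected_fraction(contact: ContactGraph) -> float:
    """Fraction of delta-cells contacting at least one beta-cell."""
    deltas = contact.cells_of_type("delta")
    if not deltas:
        raise ValueError("graph contains no delta cells: fraction undefined")
    g = contact.graph
    hit = sum(
        1
        for d in deltas
        if any(g.nodes[nb]["cell_type"] == "beta" for nb in g.neighbors(d))
    )
    return hit / len(deltas)


def neighbor_count_summary(
    contact: ContactGraph, from_type: str, to_type: str
) -> tuple[pd.Series, float]:
    """Per-cell counts of ``to_type`` neighbours for every ``from_type`` cell.

    Returns the counts (indexed by cell id) and their mean; the mean is NaN
    when there are no ``from_type`` cells.
    """
    if to_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {to_type!r}")
    g = contact.graph
    sources = contact.cells_of_type(from_type)
    counts = pd.Series(
        {
            s: sum(
                1 for nb in g.neighbors(s) if g.nodes[nb]["cell_type"] == to_type
            )
            for s in sources
        },
        dtype=int if sources else float,
        name=f"{to_type}_neighbors",
    )
    mean = float(counts.mean()) if len(counts) else float("nan")
    return counts, mean


def write_edge_list(contact: ContactGraph, path) -> None:
    """Export the edge list as tab-separated text."""
    tbl = contact.edge_table()
    tbl["distance_um"] = tbl["distance_um"].map(lambda v: f"{v:.6f}")
    tbl.to_csv(path, sep="\t", index=False)
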