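"""Co-selection matrices and co-importance graphs.

The co-selection matrix counts, for every feature pair (i, j), the number of
(selector, fold) slices in which both features were selected simultaneously;
its diagonal holds each feature's total selection count.  The co-importance
graph generalizes the counts: an edge (i, j) is weighted by

    w(i, j) = sum over selectors f and folds s of min(I[f, s, i], I[f, s, j]),

the "most limiting capacity" between the two features.  Graphs are plain
undirected :class:`networkx.Graph` objects with a ``weight`` edge attribute,
``graph["mode"]`` set to ``"co_selection"`` or ``"co_importance"``, and node
metadata (``diagonal`` selection counts or ``total_importance``).  Nodes are
restricted to features with at least one positive importance/selection, since
isolated zero features can never contribute positive induced weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .selectors import ImportanceTensor, SelectionTensor

__all__ = [
    "CoSelectionMatrix",
    "build_co_selection_matrix",
    "build_co_importance_graph",
    "co_graph_from_counts",
    "prune_graph",
    "node_strength",
    "write_edgelist",
    "read_edgelist",
    "write_node_metadata",
]


@dataclass
class CoSelectionMatrix:
    """Symmetric co-selection counts; diagonal = total selection counts."""

    feature_ids: list[str]
    M: np.ndarray
    per_selector: np.ndarray | None = None  # (F, N, N) components, on demand

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("M must be square")
        if self.M.shape[0] != len(self.feature_ids):
            raise ValueError("M size does not match feature ids")
        if (self.M < 0).any():
            raise ValueError("co-selection counts must be non-negative")
        if not np.array_equal(self.M, self.M.T):
            raise ValueError("co-selection matrix must be symmetric")
        self.M = self.M.astype(np.int64)


def build_co_selection_matrix(
    B: SelectionTensor, keep_per_selector: bool = False
) -> CoSelectionMatrix:
    """M[i, j] = number of (selector, fold) slices selecting both i and j."""
    vals = B.values.astype(np.int64)
    per_f = np.einsum("fsi,fsj->fij", vals, vals)
    M = per_f.sum(axis=0)
    return CoSelectionMatrix(
        list(B.feature_ids), M, per_selector=per_f if keep_per_selector else None
    )


def co_graph_from_counts(M: CoSelectionMatrix) -> nx.Graph:
    """Weighted co-selection graph from the positive off-diagonal counts."""
    g = nx.Graph(mode="co_selection")
    diag = np.diag(M.M)
    ids = M.feature_ids
    for i, fid in enumerate(ids):
        if diag[i] > 0:
            g.add_node(fid, diagonal=int(diag[i]))
    ii, jj = np.nonzero(np.triu(M.M, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(ids[i], ids[j], weight=float(M.M[i, j]))
    return g


def build_co_importance_graph(I: ImportanceTensor) -> nx.Graph:
    """Graph with w(i, j) = sum over slices of min(I[., i], I[., j])."""
    vals = I.values
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise ValueError("importance tensor values must lie in [0, 1]")
    totals = I.total_importance()
    keep = np.nonzero(totals > 0)[0]
    N = len(keep)
    W = np.zeros((N, N))
    sub = vals[:, :, keep]
    for f in range(vals.shape[0]):
        for s in range(vals.shape[1]):
            v = sub[f, s]
            W += np.minimum(v[:, None], v[None, :])
    ids = [I.feature_ids[i] for i in keep]
    g = nx.Graph(mode="co_importance")
    for local, i in enumerate(keep.tolist()):
        g.add_node(ids[local], total_importance=float(totals[i]))
    ii, jj = np.nonzero(np.triu(W, k=1))
    for a, b in zip(ii.tolist(), jj.tolist()):
        g.add_edge(ids[a], ids[b], weight=float(W[a, b]))
    return g


def node_strength(g: nx.Graph) -> dict:
    """Weighted degree (strength) of every node."""
    return {v: float(d) for v, d in g.degree(weight="weight")}


def prune_graph(g: nx.Graph, max_nodes: int, k: int | None = None) -> nx.Graph:
    """Keep the ``max_nodes`` highest-strength nodes (ties lexicographic)."""
    if k is not None and max_nodes < k:
        raise ValueError(f"max_nodes={max_nodes} is below the target k={k}")
    if g.number_of_nodes() <= max_nodes:
        return g
    strength = node_strength(g)
    keep = sorted(g.nodes, key=lambda v: (-strength[v], v))[:max_nodes]
    sub = g.subgraph(keep).copy()
    sub.graph.update(g.graph)
    return sub


# ---------------------------------------------------------------------------
# edge-list serialization (3-column TSV) + node metadata TSV
# ---------------------------------------------------------------------------

def write_edgelist(g: nx.Graph, path: str) -> None:
    rows = sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in g.edges(data=True)
    )
    pd.DataFrame(rows, columns=["feature_i", "feature_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist(path: str, mode: str = "co_importance") -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph(mode=mode)
    for u, v, w in df.itertuples(index=False):
        g.add_edge(str(u), str(v), weight=float(w))
    return g


def write_node_metadata(g: nx.Graph, path: str) -> None:
    strength = node_strength(g)
    rows = []
    for v in sorted(g.nodes):
        data = g.nodes[v]
        rows.append(
            (
                v,
                strength[v],
                data.get("diagonal", data.get("total_importance", "")),
            )
        )
    pd.DataFrame(rows, columns=["feature_id", "strength", "diagonal"]).to_csv(
        path, sep="\t", index=False
    )
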