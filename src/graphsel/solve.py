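"""Heaviest k-Subgraph solvers.

Given an undirected weighted graph over features, the signature is the
k-node subset maximizing the total weight of the induced edges — an NP-hard
problem.  Two solvers are provided:

* :func:`solve_exact` — depth-first branch and bound over include/exclude
  decisions on nodes ordered by decreasing strength.  The incumbent is
  initialized with the greedy solution.  The upper bound at a search node
  with r slots left is the current induced weight plus the sum of the r
  largest optimistic gains among eligible nodes, where a node's gain is its
  full connection to the chosen set plus half the sum of its (r-1) heaviest
  edges to other eligible nodes (halving avoids double counting pairs, so
  the bound is admissible).
* :func:`solve_greedy` — seed with the heaviest edge's endpoints and
  repeatedly add the node with maximal marginal induced-weight gain.

All tie-breaks are lexicographic on feature ids, so results are reproducible
across runs and platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import node_strength

__all__ = [
    "Signature",
    "ExactSolverBudgetError",
    "induced_weight",
    "solve_exact",
    "solve_greedy",
    "solve_signature",
    "write_signature",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9

_MODE_TO_METHOD = {"co_selection": "k_heavy", "co_importance": "k_w_heavy"}


class ExactSolverBudgetError(RuntimeError):
    """Raised when an instance exceeds the exact solver's node budget."""


@dataclass
class Signature:
    """A selected feature set of size k with its objective and provenance."""

    feature_ids: list[str]
    k: int
    objective: float
    method: str
    solver: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != self.k:
            raise ValueError("signature size does not match k")
        if len(set(self.feature_ids)) != self.k:
            raise ValueError("signature features must be distinct")

    def as_set(self) -> frozenset:
        return frozenset(self.feature_ids)


def induced_weight(g: nx.Graph, nodes) -> float:
    """Sum of edge weights in the subgraph induced by ``nodes``."""
    nodes = list(nodes)
    missing = [v for v in nodes if v not in g]
    if missing:
        raise ValueError(f"nodes not in graph: {missing[:5]}")
    return float(g.subgraph(nodes).size(weight="weight"))


def _method_for(g: nx.Graph, method: str | None) -> str:
    if method is not None:
        return method
    return _MODE_TO_METHOD.get(g.graph.get("mode", ""), "k_heavy")


def _check_k(g: nx.Graph, k: int) -> None:
    n = g.number_of_nodes()
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for a graph with {n} nodes")


def solve_greedy(g: nx.Graph, k: int, method: str | None = None) -> Signature:
    """Deterministic greedy heuristic; objective never exceeds the exact one."""
    _check_k(g, k)
    method = _method_for(g, method)
    if k == 1:
        strength = node_strength(g)
        best = min(g.nodes, key=lambda v: (-strength[v], v))
        return Signature([best], 1, 0.0, method, "greedy")
    edges = [
        (d["weight"], min(u, v), max(u, v))
        for u, v, d in g.edges(data=True)
        if d["weight"] > 0
    ]
    if edges:
        # among equal-weight heaviest edges prefer the lexicographically
        # smallest endpoint pair
        top_w = max(e[0] for e in edges)
        cands = sorted((u, v) for w, u, v in edges if w >= top_w - _EPS)
        u, v = cands[0]
        chosen = [u, v]
    else:
        chosen = sorted(g.nodes)[:2]
    chosen_set = set(chosen)
    while len(chosen) < k:
        gains: dict = {}
        for v in g.nodes:
            if v in chosen_set:
                continue
            gains[v] = sum(
                d["weight"] for _, nb, d in g.edges(v, data=True) if nb in chosen_set
            )
        nxt = min(gains, key=lambda v: (-gains[v], v))
        chosen.append(nxt)
        chosen_set.add(nxt)
    chosen = sorted(chosen)
    return Signature(chosen, k, induced_weight(g, chosen), method, "greedy")


def solve_exact(
    g: nx.Graph,
    k: int,
    method: str | None = None,
    node_budget: int = 500,
    collect_bounds: list | None = None,
) -> Signature:
    """Globally optimal heaviest k-subgraph via branch and bound.

    Among co-optimal subsets the lexicographically smallest id sequence is
    returned.  Instances with more than ``node_budget`` nodes raise
    :class:`ExactSolverBudgetError` (use the greedy solver instead).
    ``collect_bounds``, when a list, receives ``(chosen_ids, start, current,
    bound)`` tuples for bound-admissibility instrumentation.
    """
    _check_k(g, k)
    method = _method_for(g, method)
    n = g.number_of_nodes()
    if n > node_budget:
        raise ExactSolverBudgetError(
            f"instance has {n} nodes, above the exact-solver budget of "
            f"{node_budget}; consider solve_greedy"
        )
    strength = node_strength(g)
    nodes = sorted(g.nodes, key=lambda v: (-strength[v], v))
    W = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    ids = np.array(nodes, dtype=object)

    greedy = solve_greedy(g, k, method=method)
    best_obj = greedy.objective
    best_key = tuple(sorted(greedy.feature_ids))

    # explicit DFS stack of (next index, chosen index tuple, current weight);
    # include branch pushed last so it is explored first
    stack: list[tuple[int, tuple[int, ...], float]] = [(0, (), 0.0)]
    while stack:
        idx, chosen, cur = stack.pop()
        if len(chosen) == k:
            key = tuple(sorted(ids[list(chosen)]))
            if cur > best_obj + _EPS or (
                cur >= best_obj - _EPS and key < best_key
            ):
                best_obj, best_key = max(best_obj, cur), key
            continue
        r = k - len(chosen)
        if n - idx < r:
            continue
        elig = np.arange(idx, n)
        conn = W[np.ix_(elig, list(chosen))].sum(axis=1) if chosen else np.zeros(len(elig))
        if r > 1:
            Wee = W[np.ix_(elig, elig)]
            m = min(r - 1, len(elig) - 1)
            if m > 0 and len(elig) > 1:
                part = np.partition(Wee, len(elig) - m, axis=1)[:, len(elig) - m:]
                half = 0.5 * part.sum(axis=1)
            else:
                half = np.zeros(len(elig))
        else:
            half = np.zeros(len(elig))
        gains = conn + half
        top = np.partition(gains, len(gains) - r)[len(gains) - r:]
        bound = cur + float(top.sum())
        if collect_bounds is not None:
            collect_bounds.append(
                (tuple(ids[list(chosen)]), idx, cur, bound)
            )
        if bound < best_obj - _EPS:
            continue
        stack.append((idx + 1, chosen, cur))  # exclude nodes[idx]
        inc_w = cur + (W[idx, list(chosen)].sum() if chosen else 0.0)
        stack.append((idx + 1, chosen + (idx,), inc_w))  # include nodes[idx]
    return Signature(list(best_key), k, float(best_obj), method, "exact")


def solve_signature(
    g: nx.Graph,
    k: int,
    solver: str = "auto",
    method: str | None = None,
    node_budget: int = 500,
) -> Signature:
    """Dispatch to the exact or greedy solver; ``auto`` prefers exact."""
    if solver == "exact":
        return solve_exact(g, k, method=method, node_budget=node_budget)
    if solver == "greedy":
        return solve_greedy(g, k, method=method)
    if solver == "auto":
        if g.number_of_nodes() <= node_budget:
            return solve_exact(g, k, method=method, node_budget=node_budget)
        logger.info(
            "graph with %d nodes exceeds exact budget %d; using greedy solver",
            g.number_of_nodes(),
            node_budget,
        )
        return solve_greedy(g, k, method=method)
    raise ValueError(f"unknown solver {solver!r}")


def write_signature(
    sig: Signature,
    tsv_path: str,
    meta_path: str | None = None,
    graph: nx.Graph | None = None,
    seed: int | None = None,
) -> None:
    """Signature as TSV (rank, feature_id, strength) + JSON metadata."""
    strength = node_strength(graph) if graph is not None else {}
    rows = sorted(
        ((fid, strength.get(fid, 0.0)) for fid in sig.feature_ids),
        key=lambda r: (-r[1], r[0]),
    )
    df = pd.DataFrame(
        [(rank + 1, fid, s) for rank, (fid, s) in enumerate(rows)],
        columns=["rank", "feature_id", "strength"],
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if meta_path is not None:
        meta = {
            "k": sig.k,
            "method": sig.method,
            "solver": sig.solver,
            "objective": sig.objective,
            "seed": seed,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
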