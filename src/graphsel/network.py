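"""Interactome-based evaluation of gene signatures.

A signature of genes is assessed on a protein–protein interaction network
(PPI) by (i) its mean shortest-path distance to the disease module — the
largest connected component (LCC) induced by a disease gene list — which
should be small for disease-relevant genes, (ii) its mean pairwise
shortest-path distance, which should be large for mechanistically diverse
genes, and (iii) a hypergeometric over-representation test of its overlap
with a reference disease gene list.  Random signatures sampled without
replacement provide reference values for the distance metrics.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "DiseaseModule",
    "EnrichmentResult",
    "ModuleDistanceResult",
    "IntraSignatureResult",
    "RandomReferenceResult",
    "load_interactome",
    "extract_lcc",
    "distance_to_module",
    "intra_signature_distance",
    "random_reference",
    "hypergeom_test",
    "percent_vs_random",
]

logger = logging.getLogger(__name__)


def load_interactome(source) -> nx.Graph:
    """Undirected simple gene graph from a 2-column edge list.

    ``source`` is a path or an iterable of lines.  Self-loops and duplicate
    edges are dropped (with counts logged); symbols are whitespace-stripped
    and matched case-sensitively.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    g = nx.Graph()
    self_loops = duplicates = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed interactome row at line {lineno}: {line!r}")
        a, b = parts[0].strip(), parts[1].strip()
        if not a or not b:
            raise ValueError(f"empty gene symbol at line {lineno}")
        if a == b:
            self_loops += 1
            continue
        if g.has_edge(a, b):
            duplicates += 1
            continue
        g.add_edge(a, b)
    if self_loops or duplicates:
        logger.warning(
            "dropped %d self-loop(s) and %d duplicate edge(s)", self_loops, duplicates
        )
    if g.number_of_nodes() == 0:
        logger.warning("interactome is empty")
    logger.info(
        "interactome: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges()
    )
    return g


@dataclass
class DiseaseModule:
    """Disease gene set and its largest connected component in the PPI."""

    seed_genes: frozenset
    lcc_nodes: frozenset

    @property
    def size(self) -> int:
        return len(self.lcc_nodes)


def extract_lcc(genes, g: nx.Graph) -> DiseaseModule:
    """Largest connected induced component of the gene set in the PPI.

    Genes absent from the graph are dropped (logged); among equal-size
    components the one containing the lexicographically smallest symbol wins.
    """
    genes = {str(x).strip() for x in genes}
    if not genes:
        raise ValueError("gene set is empty")
    present = genes & set(g.nodes)
    dropped = len(genes) - len(present)
    if dropped:
        logger.info("%d gene(s) absent from the interactome", dropped)
    if not present:
        raise ValueError("no gene of the set is present in the interactome")
    comps = sorted(
        nx.connected_components(g.subgraph(present)),
        key=lambda c: (-len(c), min(c)),
    )
    return DiseaseModule(frozenset(genes), frozenset(comps[0]))


def _multi_source_bfs(g: nx.Graph, sources) -> dict:
    dist = {s: 0 for s in sources if s in g}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


@dataclass
class ModuleDistanceResult:
    mean_distance: float
    table: pd.DataFrame  # columns: gene, distance, status
    n_included: int
    n_excluded: int


def distance_to_module(signature, module: DiseaseModule, g: nx.Graph) -> ModuleDistanceResult:
    """Per gene, the hop distance to the nearest LCC node (0 inside the LCC).

    Genes absent from the PPI or unreachable from the LCC are excluded from
    the mean and reported in the per-gene table.
    """
    signature = [str(x).strip() for x in signature]
    if not signature:
        raise ValueError("signature is empty")
    dist = _multi_source_bfs(g, module.lcc_nodes)
    rows, included = [], []
    for gene in signature:
        if gene not in g:
            rows.append((gene, np.nan, "absent"))
        elif gene not in dist:
            rows.append((gene, np.nan, "unreachable"))
        else:
            d = dist[gene]
            rows.append((gene, float(d), "in_lcc" if d == 0 else "reachable"))
            included.append(d)
    if not included:
        raise ValueError("no signature gene is connected to the disease module")
    table = pd.DataFrame(rows, columns=["gene", "distance", "status"])
    return ModuleDistanceResult(
        float(np.mean(included)), table, len(included), len(rows) - len(included)
    )


@dataclass
class IntraSignatureResult:
    mean_distance: float
    n_pairs_included: int
    n_pairs_excluded: int
    n_absent_genes: int


def intra_signature_distance(signature, g: nx.Graph) -> IntraSignatureResult:
    """Mean shortest-path distance over unordered signature gene pairs.

    Unreachable pairs are excluded from the mean and counted; fewer than two
    genes present in the PPI is an error.
    """
    seen: list = []
    for x in signature:
        x = str(x).strip()
        if x not in seen:
            seen.append(x)
    present = [x for x in seen if x in g]
    n_absent = len(seen) - len(present)
    if len(present) < 2:
        raise ValueError("need at least two signature genes present in the PPI")
    dists, excluded = [], 0
    for i, a in enumerate(present):
        da = _multi_source_bfs(g, [a])
        for b in present[i + 1:]:
            if b in da:
                dists.append(da[b])
            else:
                excluded += 1
    if not dists:
        raise ValueError("no connected signature gene pair")
    return IntraSignatureResult(float(np.mean(dists)), len(dists), excluded, n_absent)


@dataclass
class RandomReferenceResult:
    per_seed: pd.DataFrame  # columns: seed, intra_signature, distance_to_module
    intra_signature_mean: float
    distance_to_module_mean: float | None


def random_reference(
    g: nx.Graph,
    n_genes: int,
    seeds,
    module: DiseaseModule | None = None,
) -> RandomReferenceResult:
    """Distance metrics of random signatures sampled without replacement.

    One signature of ``n_genes`` distinct genes is drawn per seed; per-seed
    metric values and their across-seed means are reported.
    """
    nodes = sorted(g.nodes)
    if n_genes > len(nodes):
        raise ValueError(f"cannot sample {n_genes} genes from {len(nodes)} nodes")
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        sample = list(rng.choice(nodes, size=n_genes, replace=False))
        intra = intra_signature_distance(sample, g).mean_distance
        to_mod = (
            distance_to_module(sample, module, g).mean_distance
            if module is not None
            else np.nan
        )
        rows.append((int(seed), intra, to_mod))
    df = pd.DataFrame(rows, columns=["seed", "intra_signature", "distance_to_module"])
    return RandomReferenceResult(
        df,
        float(df["intra_signature"].mean()),
        float(df["distance_to_module"].mean()) if module is not None else None,
    )


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap test between a signature and a disease list.

    ``k`` is the overlap size, ``M`` the gene universe size, ``n`` the number
    of disease-associated genes, ``N`` the signature size.
    """

    k: int
    M: int
    n: int
    N: int
    point_prob: float
    p_value: float


def hypergeom_test(k: int, M: int, n: int, N: int) -> EnrichmentResult:
    """Probability of an overlap at least as large as observed.

    ``point_prob`` is C(n, k) C(M−n, N−k) / C(M, N); ``p_value`` is the upper
    tail P(X ≥ k) including the observed overlap.
    """
    k, M, n, N = int(k), int(M), int(n), int(N)
    if not (0 <= k <= N <= M and 0 <= n <= M and k <= n):
        raise ValueError(f"invalid hypergeometric parameters k={k}, M={M}, n={n}, N={N}")
    dist = hypergeom(M, n, N)
    point = float(dist.pmf(k))
    if not np.isfinite(point):
        point = 0.0
    p_value = float(min(1.0, max(0.0, dist.sf(k - 1))))
    return EnrichmentResult(k, M, n, N, point, p_value)


def percent_vs_random(metric_value: float, random_value: float) -> float:
    """Signed percentage difference of a metric against its random reference."""
    if random_value <= 0:
        raise ValueError("random reference value must be positive")
    return 100.0 * (metric_value / random_value - 1.0)
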