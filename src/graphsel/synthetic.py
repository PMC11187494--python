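"""Synthetic study data with planted structure.

The feature-table generator emulates the regime the method targets: a small
number of informative feature *groups* (each group shares a latent class
signal and contains several redundant correlated copies) drowned in
independent pure-noise features.  Each informative feature equals
``sqrt(rho) * z_g + sqrt(1 - rho) * eps`` where ``z_g`` is the group's latent
Gaussian shifted between classes, giving within-group correlation exactly
``rho`` and a class-mean gap of ``effect_size`` standard deviations per
feature.  The toy interactome generator grows a connected scale-free-style
graph by preferential attachment and plants a connected disease module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .data import FeatureTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "generate_toy_interactome",
    "redundancy_score",
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator."""

    n_samples: int = 300
    n_groups: int = 5
    group_size: int = 3
    n_noise: int = 150
    effect_size: float = 1.5
    within_group_correlation: float = 0.9
    class_balance: float = 0.5
    seed: int = 0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.n_groups < 0 or self.group_size < 1 or self.n_noise < 0:
            raise ValueError("invalid group/noise sizes")
        if self.n_features < 1:
            raise ValueError("at least one feature is required")
        if not 0 <= self.within_group_correlation < 1:
            raise ValueError("within-group correlation must lie in [0, 1)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class balance must lie in (0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")

    @property
    def n_features(self) -> int:
        return self.n_groups * self.group_size + self.n_noise


@dataclass
class GroundTruth:
    """Group assignment (−1 = noise) and informative flag per feature."""

    feature_ids: list[str]
    group: np.ndarray
    informative: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        self.informative = np.asarray(self.informative, dtype=bool)
        if not (len(self.feature_ids) == len(self.group) == len(self.informative)):
            raise ValueError("ground-truth arrays must align with feature ids")
        if not np.array_equal(self.informative, self.group >= 0):
            raise ValueError("informative flag must match group assignment")

    def group_of(self, feature_id: str) -> int:
        return int(self.group[self.feature_ids.index(feature_id)])


def generate_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Two-class (or multi-class) table with planted informative groups."""
    rng = np.random.default_rng(spec.seed)
    n, C = spec.n_samples, spec.n_classes

    if C == 2:
        n_case = int(round(spec.class_balance * n))
        n_case = min(max(n_case, 2), n - 2)
        label_pool = np.array(["case"] * n_case + ["control"] * (n - n_case))
    else:
        base = np.arange(n) % C
        label_pool = np.array([f"class{c}" for c in base])
    labels = label_pool[rng.permutation(n)]
    classes = np.unique(label_pool)
    class_index = {c: i for i, c in enumerate(classes)}
    # equally spaced class centers, adjacent classes effect_size apart;
    # the first class (lexicographically, e.g. "case") sits on the high side
    offsets = ((len(classes) - 1) / 2 - np.arange(len(classes))) * spec.effect_size
    center = np.array([offsets[class_index[c]] for c in labels])

    rho = spec.within_group_correlation
    cols, ids, groups = [], [], []
    for gi in range(spec.n_groups):
        if rho > 0:
            z = rng.standard_normal(n) + center / np.sqrt(rho)
            shared = np.sqrt(rho) * z
        for ci in range(spec.group_size):
            eps = rng.standard_normal(n)
            if rho > 0:
                col = shared + np.sqrt(1 - rho) * eps
            else:
                col = center + eps
            cols.append(col)
            ids.append(f"g{gi + 1:02d}_r{ci + 1}")
            groups.append(gi)
    for j in range(spec.n_noise):
        cols.append(rng.standard_normal(n))
        ids.append(f"noise{j + 1:04d}")
        groups.append(-1)
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    table = FeatureTable(sample_ids, ids, values, labels)
    truth = GroundTruth(ids, np.array(groups), np.array(groups) >= 0)
    return table, truth


def generate_toy_interactome(
    n_nodes: int = 200,
    attach_param: int = 3,
    module_size: int = 15,
    seed: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Connected preferential-attachment graph with a planted disease module.

    The disease module is a connected set of ``module_size`` genes collected
    by deterministic breadth-first search from the highest-degree node.
    """
    if attach_param < 1:
        raise ValueError("attach_param must be at least 1")
    if not 1 <= module_size < n_nodes:
        raise ValueError("module_size must lie in [1, n_nodes)")
    if n_nodes <= attach_param:
        raise ValueError("n_nodes must exceed attach_param")
    raw = nx.barabasi_albert_graph(n_nodes, attach_param, seed=int(seed))
    width = len(str(n_nodes - 1))
    mapping = {i: f"G{i:0{width}d}" for i in raw.nodes}
    g = nx.relabel_nodes(raw, mapping)
    start = sorted(g.nodes, key=lambda v: (-g.degree(v), v))[0]
    module, queue = [start], [start]
    seen = {start}
    while queue and len(module) < module_size:
        u = queue.pop(0)
        for v in sorted(g[u]):
            if v not in seen:
                seen.add(v)
                module.append(v)
                queue.append(v)
                if len(module) == module_size:
                    break
    return g, sorted(module)


def redundancy_score(signature, truth: GroundTruth) -> tuple[int, int]:
    """(distinct informative groups hit, within-group duplicate pairs)."""
    features = getattr(signature, "feature_ids", signature)
    known = set(truth.feature_ids)
    missing = [f for f in features if f not in known]
    if missing:
        raise ValueError(f"signature features unknown to the ground truth: {missing[:5]}")
    groups = [truth.group_of(f) for f in features]
    informative = [gid for gid in groups if gid >= 0]
    n_hit = len(set(informative))
    n_dup = sum(1 for a, b in combinations(informative, 2) if a == b)
    return n_hit, n_dup
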