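"""scikit-learn estimators for ensemble feature selection.

The selectors follow the SelectorMixin contract: ``fit(X, y)`` runs the base
selector roster on internal stratified cross-validation folds of the training
data, aggregates the evidence (into a co-importance or co-selection graph, or
into marginal counts/means for the voting baselines) and stores a boolean
support mask, so the estimators compose with sklearn pipelines and model
selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .baselines import mv_select, wmv_select
from .data import make_cv_folds
from .graph import (
    build_co_importance_graph,
    build_co_selection_matrix,
    co_graph_from_counts,
    prune_graph,
)
from .selectors import DEFAULT_ROSTER, binarize, build_importance_tensor
from .solve import Signature, solve_signature

__all__ = [
    "GraphicalEnsembleSelector",
    "MajorityVoteSelector",
    "WeightedMajorityVoteSelector",
]


class _BaseEnsembleSelector(SelectorMixin, BaseEstimator):
    """Shared fitting logic: folds → importance tensor → signature."""

    def __init__(
        self,
        k=10,
        selector_roster=None,
        n_folds=5,
        per_fold_budget=None,
        random_state=None,
    ):
        self.k = k
        self.selector_roster = selector_roster
        self.n_folds = n_folds
        self.per_fold_budget = per_fold_budget
        self.random_state = random_state

    def _budget(self) -> int:
        if self.per_fold_budget is not None:
            return int(self.per_fold_budget)
        return max(1, 2 * int(self.k))

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=np.float64)
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k={self.k} out of range for {X.shape[1]} features")
        seed = 0 if self.random_state is None else int(self.random_state)
        if hasattr(self, "feature_names_in_"):
            feature_ids = [str(f) for f in self.feature_names_in_]
        else:
            width = max(4, len(str(X.shape[1] - 1)))
            feature_ids = [f"x{i:0{width}d}" for i in range(X.shape[1])]
        folds = make_cv_folds(y, seed=seed, n_folds=self.n_folds)
        tensor = build_importance_tensor(
            X,
            folds,
            roster=self.selector_roster or DEFAULT_ROSTER,
            random_state=seed,
            labels=y,
            feature_ids=feature_ids,
        )
        self.importance_tensor_ = tensor
        self.signature_ = self._select_signature(tensor)
        idx = {f: i for i, f in enumerate(feature_ids)}
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[[idx[f] for f in self.signature_.feature_ids]] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _select_signature(self, tensor) -> Signature:  # pragma: no cover
        raise NotImplementedError


class GraphicalEnsembleSelector(_BaseEnsembleSelector):
    """Heaviest-k-subgraph signature on the co-importance/co-selection graph.

    Parameters
    ----------
    k : int
        Signature size.
    mode : {"k_w_heavy", "k_heavy"}
        ``k_w_heavy`` optimizes the co-importance graph (summed pairwise
        minimum importances); ``k_heavy`` optimizes the co-selection counts
        graph built from top-``per_fold_budget`` binarized selections.
    selector_roster : list of str, optional
        Base selector ids; defaults to the seven-technique roster.
    n_folds : int
        Internal stratified cross-validation folds.
    per_fold_budget : int, optional
        Binarization budget t; defaults to 2k.
    solver : {"auto", "exact", "greedy"}
        ``auto`` uses the exact branch-and-bound solver up to
        ``exact_node_budget`` graph nodes, the greedy heuristic above it.
    max_graph_nodes : int, optional
        Prune the graph to this many highest-strength nodes before solving.
    random_state : int, optional
        Seed threaded into every stochastic base selector and fold split.

    Attributes
    ----------
    signature_ : Signature
        Selected features with the induced-weight objective.
    support_ : ndarray of bool
        Selection mask over the input features.
    graph_ : networkx.Graph
        The (possibly pruned) weighted feature graph that was optimized.
    """

    def __init__(
        self,
        k=10,
        mode="k_w_heavy",
        selector_roster=None,
        n_folds=5,
        per_fold_budget=None,
        solver="auto",
        max_graph_nodes=None,
        exact_node_budget=500,
        random_state=None,
    ):
        super().__init__(
            k=k,
            selector_roster=selector_roster,
            n_folds=n_folds,
            per_fold_budget=per_fold_budget,
            random_state=random_state,
        )
        self.mode = mode
        self.solver = solver
        self.max_graph_nodes = max_graph_nodes
        self.exact_node_budget = exact_node_budget

    def _select_signature(self, tensor) -> Signature:
        if self.mode == "k_heavy":
            g = co_graph_from_counts(
                build_co_selection_matrix(binarize(tensor, self._budget()))
            )
        elif self.mode == "k_w_heavy":
            g = build_co_importance_graph(tensor)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_graph_nodes is not None:
            g = prune_graph(g, self.max_graph_nodes, k=self.k)
        self.graph_ = g
        if g.number_of_nodes() < self.k:
            # graph smaller than k (few features ever scored): solve on what
            # is there, pad with the lexicographically smallest leftovers
            ids: set = set()
            if g.number_of_nodes() >= 1:
                sub = solve_signature(
                    g,
                    g.number_of_nodes(),
                    solver=self.solver,
                    node_budget=self.exact_node_budget,
                )
                ids.update(sub.feature_ids)
            for f in sorted(tensor.feature_ids):
                if len(ids) == self.k:
                    break
                ids.add(f)
            obj = float(g.subgraph([f for f in ids if f in g]).size(weight="weight"))
            return Signature(sorted(ids), self.k, obj, self.mode, self.solver)
        return solve_signature(
            g, self.k, solver=self.solver, node_budget=self.exact_node_budget
        )


class MajorityVoteSelector(_BaseEnsembleSelector):
    """Top-k features by total selection count across selectors and folds."""

    def _select_signature(self, tensor) -> Signature:
        return mv_select(binarize(tensor, self._budget()), self.k)


class WeightedMajorityVoteSelector(_BaseEnsembleSelector):
    """Top-k features by mean importance across selectors and folds."""

    def _select_signature(self, tensor) -> Signature:
        return wmv_select(tensor, self.k)
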