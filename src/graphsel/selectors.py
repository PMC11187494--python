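"""Base feature-selection techniques run per cross-validation fold.

Each registered selector maps a (training matrix, training labels) pair to one
non-negative raw score per feature.  Raw scores are rescaled per
(selector, fold) slice so the maximum is 1 (an all-zero slice stays zero),
which makes heterogeneous selectors commensurable when their importances are
summed into a co-importance graph.  Binarization turns a slice into a
selection event: the ``t`` highest-importance features of the slice, ties
broken by lexicographic feature id.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE, chi2, f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .data import FeatureTable, SplitPlan
from .preprocess import ZScoreNormalizer

__all__ = [
    "ImportanceTensor",
    "SelectionTensor",
    "DEFAULT_ROSTER",
    "register_selector",
    "run_selector",
    "normalize_importance",
    "build_importance_tensor",
    "binarize",
    "save_tensor",
    "load_tensor",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tensors
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTensor:
    """Importance weights I[f, s, i] in [0, 1].

    Dimensions are selector (f), cross-validation fold (s) and feature (i).
    Slices produced by :func:`build_importance_tensor` additionally have
    max == 1 unless all-zero (the normalization contract).
    """

    selector_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.selector_ids = [str(s) for s in self.selector_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3-d (selector, fold, feature)")
        f, _, i = self.values.shape
        if f != len(self.selector_ids) or i != len(self.feature_ids):
            raise ValueError("tensor dimensions do not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite values")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("importance values must lie in [0, 1]")

    @property
    def n_selectors(self) -> int:
        return self.values.shape[0]

    @property
    def n_folds(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def total_importance(self) -> np.ndarray:
        """Per-feature sum of importances over all (selector, fold) slices."""
        return self.values.sum(axis=(0, 1))


@dataclass
class SelectionTensor:
    """Binary selection indicators B[f, s, i] with per-fold budget ``t``."""

    selector_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    per_fold_budget: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("selection tensor must be binary")
        self.values = self.values.astype(np.uint8)
        if self.per_fold_budget < 1:
            raise ValueError("per-fold budget must be at least 1")
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3-d (selector, fold, feature)")

    @property
    def n_selectors(self) -> int:
        return self.values.shape[0]

    @property
    def n_folds(self) -> int:
        return self.values.shape[1]

    def selection_counts(self) -> np.ndarray:
        """Per-feature total selection count over all (selector, fold)."""
        return self.values.sum(axis=(0, 1), dtype=np.int64)


# ---------------------------------------------------------------------------
# selector registry
# ---------------------------------------------------------------------------

_REGISTRY: dict = {}


def register_selector(name: str):
    """Decorator registering ``fn(X, y, random_state) -> raw scores``."""

    def deco(fn):
        _REGISTRY[name] = fn
        return fn

    return deco


@register_selector("anova_f")
def _anova_f(X, y, random_state):
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, _ = f_classif(X, y)
    return f


@register_selector("mutual_info")
def _mutual_info(X, y, random_state):
    return mutual_info_classif(X, y, random_state=random_state)


@register_selector("abs_correlation")
def _abs_correlation(X, y, random_state):
    # numeric label encoding in lexicographic class order
    y_num = LabelEncoder().fit_transform(y).astype(np.float64)
    xc = X - X.mean(axis=0)
    yc = y_num - y_num.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.abs(r)


@register_selector("l1_logistic")
def _l1_logistic(X, y, random_state):
    clf = LogisticRegression(
        l1_ratio=1, solver="liblinear", C=1.0, max_iter=1000,
        random_state=random_state,
    )
    clf.fit(X, y)
    return np.abs(clf.coef_).sum(axis=0)


@register_selector("l1_svm")
def _l1_svm(X, y, random_state):
    clf = LinearSVC(
        penalty="l1", dual=False, C=1.0, max_iter=5000, random_state=random_state
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return np.abs(clf.coef_).sum(axis=0)


@register_selector("decision_tree")
def _decision_tree(X, y, random_state):
    clf = DecisionTreeClassifier(random_state=random_state)
    clf.fit(X, y)
    return clf.feature_importances_


@register_selector("gradient_boosting")
def _gradient_boosting(X, y, random_state):
    clf = GradientBoostingClassifier(n_estimators=50, random_state=random_state)
    clf.fit(X, y)
    return clf.feature_importances_


@register_selector("random_forest")
def _random_forest(X, y, random_state):
    clf = RandomForestClassifier(
        n_estimators=100, random_state=random_state, n_jobs=1
    )
    clf.fit(X, y)
    return clf.feature_importances_


# per-fold subset size for the explicitly subset-proposing techniques
_SUBSET_BUDGET = 25


@register_selector("mrmr")
def _mrmr(X, y, random_state):
    """Greedy max-relevance min-redundancy: rank by F-score relevance minus
    mean absolute correlation with the already-chosen set; the importance of
    a picked feature is its score at pick time, unpicked features score 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, _ = f_classif(X, y)
    rel = np.nan_to_num(f, nan=0.0, posinf=0.0, neginf=0.0)
    if rel.max() > 0:
        rel = rel / rel.max()
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0)
    corr = np.abs(Xs.T @ Xs / X.shape[0])
    n = X.shape[1]
    chosen: list[int] = []
    scores = np.zeros(n)
    available = np.ones(n, dtype=bool)
    for _ in range(min(_SUBSET_BUDGET, n)):
        sc = rel.copy() if not chosen else rel - corr[:, chosen].mean(axis=1)
        sc[~available] = -np.inf
        j = int(np.argmax(sc))
        if chosen and sc[j] <= 0:
            break
        scores[j] = max(float(sc[j]), 1e-6)
        chosen.append(j)
        available[j] = False
    return scores


@register_selector("rfe_logistic")
def _rfe_logistic(X, y, random_state):
    est = LogisticRegression(max_iter=1000, random_state=random_state)
    n_keep = min(_SUBSET_BUDGET, X.shape[1])
    rfe = RFE(est, n_features_to_select=n_keep, step=0.2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rfe.fit(X, y)
    imp = np.zeros(X.shape[1])
    imp[rfe.support_] = np.abs(rfe.estimator_.coef_).sum(axis=0)
    return imp


@register_selector("variance")
def _variance(X, y, random_state):
    if X.shape[0] < 2:
        return np.zeros(X.shape[1])
    return X.var(axis=0, ddof=1)


@register_selector("chi2_shifted")
def _chi2_shifted(X, y, random_state):
    Xs = X - X.min(axis=0)  # chi-squared needs non-negative inputs
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score, _ = chi2(Xs, y)
    return score


# Seven techniques spanning embedded, wrapper and redundancy-aware filter
# paradigms.  Every default technique concentrates its weight on a
# low-redundancy subset per split (sparse linear models, greedy trees,
# explicit redundancy penalties): the co-importance aggregation assumes the
# base selections are complementary, and redundancy-blind univariate filters
# (anova_f, mutual_info, abs_correlation, chi2_shifted, variance — still
# registered and available) score correlated copies of one signal jointly,
# which makes the ensemble favour redundant cliques instead of eliminating
# them.
DEFAULT_ROSTER = [
    "l1_logistic",
    "l1_svm",
    "decision_tree",
    "gradient_boosting",
    "random_forest",
    "mrmr",
    "rfe_logistic",
]


def run_selector(
    selector_id: str,
    train_values: np.ndarray,
    train_labels: np.ndarray,
    random_state: int = 0,
) -> np.ndarray:
    """Raw non-negative importance scores for one selector on one fold."""
    if selector_id not in _REGISTRY:
        raise ValueError(
            f"unknown selector {selector_id!r}; registered: {sorted(_REGISTRY)}"
        )
    X = np.asarray(train_values, dtype=np.float64)
    y = np.asarray(train_labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    if np.allclose(X, X[0], atol=1e-12):
        warnings.warn(
            f"constant training matrix for selector {selector_id!r}; "
            "returning all-zero scores",
            UserWarning,
            stacklevel=2,
        )
        return np.zeros(X.shape[1])
    raw = np.asarray(_REGISTRY[selector_id](X, y, random_state), dtype=np.float64)
    raw = np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0)
    raw[raw < 0] = 0.0
    # zero-variance features carry no information regardless of the selector
    constant = X.std(axis=0) <= 1e-12
    raw[constant] = 0.0
    return raw


def normalize_importance(raw: np.ndarray) -> np.ndarray:
    """Scale a raw score vector so its maximum is 1 (all-zero unchanged)."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)) or (raw < 0).any():
        raise ValueError("raw importances must be finite and non-negative")
    m = raw.max() if raw.size else 0.0
    if m <= 0:
        return raw.copy()
    return raw / m


def _as_folds(plan) -> list:
    if isinstance(plan, SplitPlan):
        return plan.folds
    return list(plan)


def build_importance_tensor(
    table,
    plan,
    roster: list[str] | None = None,
    random_state: int = 0,
    labels: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
    normalize_per_fold: bool = True,
) -> ImportanceTensor:
    """Run the roster on each fold's training rows and normalize per slice.

    ``table`` may be a :class:`FeatureTable` or a plain matrix (then
    ``labels`` is required).  When ``normalize_per_fold`` is set, each fold's
    training rows are z-scored with statistics from those rows only before
    the selectors see them, so no validation or test information enters the
    fit.  A selector failure on a fold is recorded as an all-zero slice with
    a warning rather than aborting the run.
    """
    roster = list(roster) if roster is not None else list(DEFAULT_ROSTER)
    if not roster:
        raise ValueError("selector roster must be non-empty")
    if isinstance(table, FeatureTable):
        values, labels = table.values, table.labels
        feature_ids = feature_ids or table.feature_ids
    else:
        values = np.asarray(table, dtype=np.float64)
        if labels is None:
            raise ValueError("labels are required when table is a plain matrix")
    if feature_ids is None:
        width = max(4, len(str(values.shape[1] - 1)))
        feature_ids = [f"x{i:0{width}d}" for i in range(values.shape[1])]
    folds = _as_folds(plan)
    F, S, N = len(roster), len(folds), values.shape[1]
    tensor = np.zeros((F, S, N))
    for s, (train_idx, _val_idx) in enumerate(folds):
        Xtr = values[np.asarray(train_idx, dtype=int)]
        ytr = np.asarray(labels)[np.asarray(train_idx, dtype=int)]
        if normalize_per_fold:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                Xtr = ZScoreNormalizer().fit_transform(Xtr)
        for f, sel in enumerate(roster):
            try:
                raw = run_selector(sel, Xtr, ytr, random_state=random_state)
            except Exception as exc:  # recorded, not fatal
                warnings.warn(
                    f"selector {sel!r} failed on fold {s}: {exc}; "
                    "recording an all-zero slice",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            tensor[f, s] = normalize_importance(raw)
    return ImportanceTensor(roster, list(feature_ids), tensor)


def binarize(tensor: ImportanceTensor, t: int) -> SelectionTensor:
    """Mark the top-``t`` features of each (selector, fold) slice as selected.

    Ties are broken by lexicographic feature id; zero-importance features are
    never selected, so a slice with fewer than ``t`` positive importances
    yields fewer than ``t`` ones.
    """
    if t < 1:
        raise ValueError("per-fold budget t must be at least 1")
    N = tensor.n_features
    if t > N:
        warnings.warn(
            f"budget t={t} exceeds {N} features; clamping", UserWarning, stacklevel=2
        )
        t = N
    # rank of each feature id in lexicographic order, used as tie-break key
    lex_rank = np.argsort(np.argsort(np.asarray(tensor.feature_ids)))
    B = np.zeros_like(tensor.values, dtype=np.uint8)
    for f in range(tensor.n_selectors):
        for s in range(tensor.n_folds):
            v = tensor.values[f, s]
            order = np.lexsort((lex_rank, -v))  # by value desc, then id asc
            chosen = [i for i in order[:t] if v[i] > 0]
            B[f, s, chosen] = 1
    return SelectionTensor(tensor.selector_ids, tensor.feature_ids, B, t)


# ---------------------------------------------------------------------------
# persistence: compressed array archive + JSON sidecar of dimension labels
# ---------------------------------------------------------------------------

def save_tensor(tensor, path: str) -> None:
    np.savez_compressed(path, values=tensor.values)
    meta = {
        "selector_ids": tensor.selector_ids,
        "feature_ids": tensor.feature_ids,
        "kind": "selection" if isinstance(tensor, SelectionTensor) else "importance",
    }
    if isinstance(tensor, SelectionTensor):
        meta["per_fold_budget"] = tensor.per_fold_budget
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_tensor(path: str):
    path = str(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    values = np.load(path)["values"]
    with open(path[:-4] + ".json") as fh:
        meta = json.load(fh)
    if meta["kind"] == "selection":
        return SelectionTensor(
            meta["selector_ids"], meta["feature_ids"], values, meta["per_fold_budget"]
        )
    return ImportanceTensor(meta["selector_ids"], meta["feature_ids"], values)
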