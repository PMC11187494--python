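"""Labeled feature tables and leakage-free split plans.

A :class:`FeatureTable` is the in-memory form of the delimited-text input
format: one row per sample, a sample-id column first, real-valued feature
columns, and a categorical label column last.  A :class:`SplitPlan` fixes a
stratified test holdout plus stratified cross-validation folds on the
remainder; everything downstream (normalization, selector fitting, classifier
training) is a function of fold-training rows only.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "FeatureTable",
    "SplitPlan",
    "make_split_plan",
    "make_cv_folds",
    "read_feature_table",
    "write_feature_table",
]


@dataclass
class FeatureTable:
    """Samples × features matrix with sample ids, feature ids and labels."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows of values"
            )
        if p != len(self.feature_ids):
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {p} columns of values"
            )
        if len(self.labels) != n:
            raise ValueError("labels length does not match number of samples")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("at least two distinct label values are required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict:
        return dict(collections.Counter(self.labels.tolist()))


@dataclass
class SplitPlan:
    """Stratified test holdout + cross-validation folds, fixed by a seed.

    ``folds`` is a list of ``(train_index, validation_index)`` integer-array
    pairs over the non-test rows; ``test_index`` is disjoint from every fold.
    """

    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    test_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.test_index = np.asarray(self.test_index, dtype=int)
        test = set(self.test_index.tolist())
        norm = []
        for tr, va in self.folds:
            tr = np.asarray(tr, dtype=int)
            va = np.asarray(va, dtype=int)
            str_, sva = set(tr.tolist()), set(va.tolist())
            if str_ & sva:
                raise ValueError("train and validation indices overlap in a fold")
            if (str_ | sva) & test:
                raise ValueError("test indices leak into a cross-validation fold")
            norm.append((tr, va))
        self.folds = norm

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def trainval_index(self) -> np.ndarray:
        """All non-test indices, sorted."""
        idx: set[int] = set()
        for tr, va in self.folds:
            idx.update(tr.tolist())
            idx.update(va.tolist())
        return np.array(sorted(idx), dtype=int)


def _check_class_sizes(labels: np.ndarray, n_folds: int) -> None:
    counts = collections.Counter(np.asarray(labels).tolist())
    for cls, cnt in counts.items():
        if cnt < n_folds:
            raise ValueError(
                f"class {cls!r} has only {cnt} samples, fewer than n_folds={n_folds}"
            )


def make_cv_folds(
    labels: np.ndarray, seed: int, n_folds: int = 5
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold train/validation index pairs over all rows."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    _check_class_sizes(labels, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    idx = np.arange(len(labels))
    return [(idx[tr], idx[va]) for tr, va in skf.split(idx.reshape(-1, 1), labels)]


def make_split_plan(
    table: FeatureTable,
    seed: int,
    n_folds: int = 5,
    test_fraction: float = 0.2,
) -> SplitPlan:
    """Stratified test holdout then stratified K-fold CV on the remainder."""
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if not 0.0 < test_fraction < 0.5:
        raise ValueError("test_fraction must lie in (0, 0.5)")
    labels = table.labels
    idx = np.arange(table.n_samples)
    trainval, test = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    trainval = np.sort(trainval)
    _check_class_sizes(labels[trainval], n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [
        (trainval[tr], trainval[va])
        for tr, va in skf.split(trainval.reshape(-1, 1), labels[trainval])
    ]
    return SplitPlan(seed=seed, folds=folds, test_index=np.sort(test))


def _infer_sep(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_feature_table(path: str, sep: str | None = None) -> FeatureTable:
    """Read a delimited table: sample-id column first, label column last."""
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError("expected at least sample id, one feature, and a label column")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, -1].to_numpy()
    feature_ids = [str(c) for c in df.columns[1:-1]]
    values = df.iloc[:, 1:-1].to_numpy(dtype=np.float64)
    return FeatureTable(sample_ids, feature_ids, values, labels)


def write_feature_table(table: FeatureTable, path: str, sep: str | None = None) -> None:
    sep = sep or _infer_sep(path)
    df = pd.DataFrame(table.values, columns=table.feature_ids)
    df.insert(0, "sample_id", table.sample_ids)
    df["label"] = table.labels
    df.to_csv(path, sep=sep, index=False)
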