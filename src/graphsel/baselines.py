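"""Majority-voting ensemble feature-selection baselines.

MV keeps the top-k features by total selection count across all selectors
and folds; WMV keeps the top-k by average importance weight.  Both use only
the marginal (per-feature) information, i.e. the diagonal of the
co-selection matrix — they are the ablations of the graph-based method that
ignore co-occurrence structure.
"""

from __future__ import annotations

import numpy as np

from .selectors import ImportanceTensor, SelectionTensor
from .solve import Signature

__all__ = ["mv_select", "wmv_select"]


def _top_k(feature_ids: list[str], scores: np.ndarray, k: int) -> list[int]:
    lex_rank = np.argsort(np.argsort(np.asarray(feature_ids)))
    order = np.lexsort((lex_rank, -scores))
    return order[:k].tolist()


def mv_select(B: SelectionTensor, k: int) -> Signature:
    """Top-k features by total selection count (ties lexicographic)."""
    n = len(B.feature_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} features")
    counts = B.selection_counts().astype(np.float64)
    idx = _top_k(B.feature_ids, counts, k)
    ids = sorted(B.feature_ids[i] for i in idx)
    return Signature(ids, k, float(counts[idx].sum()), "mv", "exact")


def wmv_select(
    I: ImportanceTensor, k: int, include_zero_slices: bool = True
) -> Signature:
    """Top-k features by mean importance over all (selector, fold) slices.

    With ``include_zero_slices`` (default) the mean runs over all F×S slices,
    so a feature unscored by a selector contributes 0; otherwise only slices
    with any positive importance for the feature enter its mean.
    """
    n = len(I.feature_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} features")
    if include_zero_slices:
        means = I.values.mean(axis=(0, 1))
    else:
        pos = I.values > 0
        denom = np.maximum(pos.sum(axis=(0, 1)), 1)
        means = I.values.sum(axis=(0, 1)) / denom
    idx = _top_k(I.feature_ids, means, k)
    ids = sorted(I.feature_ids[i] for i in idx)
    return Signature(ids, k, float(means[idx].sum()), "wmv", "exact")
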