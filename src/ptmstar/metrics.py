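"""Recall, precision and AUC for checkpoint selection and consensus evaluation.

AUC is the Mann-Whitney statistic: over all positive-negative pairs, the
fraction where the positive scores higher, with ties counted as 0.5.  The
tie rule matters here because consensus vote sums are small integers, so
tied scores are the norm rather than the exception.  The implementation is
rank-based (O(n log n)) via scipy's midrank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class EvalResult:
    auc: float
    recall: float
    precision: float
    n_pos: int
    n_neg: int


def recall(pred_binary, labels) -> float:
    """TP / (TP + FN).  Requires at least one positive label."""
    pred = np.asarray(pred_binary, dtype=int)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("recall undefined: no positive labels")
    tp = int(((pred == 1) & (y == 1)).sum())
    return tp / n_pos


def precision(pred_binary, labels) -> float:
    """TP / (TP + FP); 0.0 when there are no positive predictions."""
    pred = np.asarray(pred_binary, dtype=int)
    y = np.asarray(labels, dtype=int)
    n_pred_pos = int((pred == 1).sum())
    if n_pred_pos == 0:
        return 0.0
    tp = int(((pred == 1) & (y == 1)).sum())
    return tp / n_pred_pos


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted as 0.5.

    Computed from midranks: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg)
    where R_pos is the rank sum of the positive scores.  Requires both
    classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: needs both classes")
    ranks = rankdata(s)  # midranks handle ties as 0.5 per pair
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(scores, labels, threshold: float = 0.5) -> EvalResult:
    """All three metrics at once, thresholding scores at ``threshold``
    (score >= threshold predicts positive)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (s >= threshold).astype(int)
    return EvalResult(
        auc=auc(s, y),
        recall=recall(pred, y),
        precision=precision(pred, y),
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
    )
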