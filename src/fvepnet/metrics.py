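"""Binary classification metrics: confusion-matrix rates and rank AUC."""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


class MetricsError(ValueError):
    pass


@dataclasses.dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    support_positive: int = 0
    support_negative: int = 0
    zero_division: bool = False

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> MetricsReport:
    """Accuracy / precision / recall / F1 from the 2x2 table.

    Division-by-zero rates (no predicted positives, no true positives) are
    reported as 0 with ``zero_division`` flagged.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0:
        raise MetricsError("empty input")
    if yt.shape != yp.shape:
        raise MetricsError("y_true and y_pred lengths differ")
    if not (set(np.unique(yt)) <= {0, 1} and set(np.unique(yp)) <= {0, 1}):
        raise MetricsError("labels must be binary {0,1}")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    n = tp + fp + fn + tn
    zero_div = False
    acc = (tp + tn) / n
    if tp + fp > 0:
        prec = tp / (tp + fp)
    else:
        prec, zero_div = 0.0, True
    if tp + fn > 0:
        rec = tp / (tp + fn)
    else:
        rec, zero_div = 0.0, True
    if prec + rec > 0:
        f1 = 2 * prec * rec / (prec + rec)
    else:
        f1, zero_div = 0.0, True
    if zero_div:
        warnings.warn("zero-division in precision/recall/F1 reported as 0", stacklevel=2)
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=acc, precision=prec, recall=rec, f1=f1,
        support_positive=tp + fn, support_negative=tn + fp,
        zero_division=zero_div,
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC of scores against binary labels.

    Ties receive midranks, so identical scores for all records give 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("AUC requires both classes present")
    ranks = rankdata(s)
    u = np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
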