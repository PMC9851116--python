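"""Out-of-distribution detection.

Five detectors, all emitting scores oriented so that HIGHER = more likely
out-of-distribution:

* ``confidence`` — 1 - c from the network's confidence head (the method under
  study; needs no extra fit);
* ``entropy``    — Shannon entropy of the softmax output (training-free
  baseline);
* ``lof`` / ``ocsvm`` / ``mcd`` — classical novelty detectors fitted on the
  penultimate (fusion-layer) embeddings of the in-distribution training
  records, scored as the negated sklearn ``score_samples`` (LOF/OCSVM) or the
  robust Mahalanobis distance (MCD).

Thresholds are chosen on training-side scores (max-F1 over the observed score
grid) and frozen before computing test metrics.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.covariance import MinCovDet
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

from .metrics import MetricsError, auc as rank_auc

METHODS = ("confidence", "entropy", "lof", "ocsvm", "mcd")


class OodError(ValueError):
    pass


@dataclasses.dataclass
class OodScore:
    scores: np.ndarray
    method: str
    threshold: float | None = None

    def flags(self, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise OodError("no threshold set for this score")
        return (self.scores > thr).astype(int)


def confidence_score(c: Sequence[float]) -> OodScore:
    """1 - c: a sweep the network is unsure about scores high."""
    return OodScore(scores=1.0 - np.asarray(c, dtype=float), method="confidence")


def entropy_score(p: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Shannon entropy -sum p_i ln p_i per row (natural log)."""
    p = np.asarray(p, dtype=float)
    pc = np.clip(p, eps, 1.0)
    h = -(pc * np.log(pc)).sum(axis=-1)
    return h if h.ndim else float(h)


def entropy_scores(p: np.ndarray) -> OodScore:
    return OodScore(scores=np.atleast_1d(entropy_score(p)), method="entropy")


class FeatureDetector:
    """Novelty detector over penultimate embeddings, uniform orientation."""

    def __init__(self, kind: str, model, method: str, projection=None):
        self._kind = kind
        self._model = model
        self._projection = projection
        self.method = method

    def score(self, embeddings: np.ndarray) -> OodScore:
        x = np.asarray(embeddings, dtype=float)
        if self._projection is not None:
            x = self._projection.transform(x)
        if self._kind == "mcd":
            s = self._model.mahalanobis(x)
        else:
            s = -self._model.score_samples(x)
        return OodScore(scores=np.asarray(s, dtype=float), method=self.method)


def fit_feature_detector(
    kind: str,
    embeddings: np.ndarray,
    n_neighbors: int = 20,
    nu: float = 0.1,
    support_fraction: float | None = None,
    seed: int = 0,
) -> FeatureDetector:
    """Fit LOF / one-class SVM / minimum covariance determinant on the
    in-distribution training embeddings."""
    x = np.asarray(embeddings, dtype=float)
    if kind not in ("lof", "ocsvm", "mcd"):
        raise OodError(f"unknown detector kind {kind!r}")
    minimum = {"lof": n_neighbors + 1, "ocsvm": 2, "mcd": 8}[kind]
    if x.shape[0] < minimum:
        raise OodError(f"{kind} needs at least {minimum} embeddings, got {x.shape[0]}")
    projection = None
    if kind == "lof":
        m = LocalOutlierFactor(n_neighbors=n_neighbors, novelty=True).fit(x)
    elif kind == "ocsvm":
        m = OneClassSVM(nu=nu, kernel="rbf", gamma="scale").fit(x)
    else:
        if x.shape[0] <= 2 * x.shape[1]:
            # robust covariance needs n >> d; compress the (ReLU-sparse)
            # embedding cloud before estimating it
            from sklearn.decomposition import PCA

            projection = PCA(
                n_components=max(2, min(x.shape[1], x.shape[0] // 2)), random_state=seed
            ).fit(x)
            x = projection.transform(x)
        m = MinCovDet(support_fraction=support_fraction, random_state=seed).fit(x)
    return FeatureDetector(kind, m, kind, projection)


def choose_threshold(scores_in: OodScore, scores_out: OodScore):
    """Max-F1 threshold over the union score grid, plus the ranking AUC.

    OOD is the positive class.  Returns ``(threshold, f1, auc)``.
    """
    si = np.asarray(scores_in.scores, dtype=float)
    so = np.asarray(scores_out.scores, dtype=float)
    if si.size == 0 or so.size == 0:
        raise OodError("both score sets must be non-empty")
    allscores = np.concatenate([si, so])
    labels = np.concatenate([np.zeros(si.size, dtype=int), np.ones(so.size, dtype=int)])
    uniq = np.unique(allscores)
    if uniq.size == 1:
        raise OodError("all scores identical: threshold undefined")
    # candidate cuts: midpoints between consecutive distinct scores
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best_thr, best_f1 = cands[0], -1.0
    n_pos = so.size
    for thr in cands:
        pred = allscores > thr
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = n_pos - tp
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    try:
        a = rank_auc(allscores, labels)
    except MetricsError:  # pragma: no cover - guarded above
        a = float("nan")
    return best_thr, best_f1, a
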