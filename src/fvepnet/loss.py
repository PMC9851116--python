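"""Confidence-hinted focal loss.

The total training objective is ``L = mean(Lt) + lambda * mean(Lc)`` where

* the *hinted* probabilities interpolate the softmax output toward the true
  one-hot label by the confidence scalar, ``p_hat = c*p + (1-c)*y`` — for a
  randomly chosen fraction of each batch only, so the network cannot rely on
  the hint being present;
* ``Lt`` is a focal-loss variant of cross-entropy on ``p_hat``: the positive
  class term is down-weighted by ``(1-p_hat)**gamma``, blunting the dominance
  of easy majority-class examples.  By default the negative-class term carries
  no ``gamma`` exponent (``symmetric_gamma=True`` switches to the standard
  focal form where it does);
* ``Lc = -log(c)`` penalises low confidence, preventing the degenerate
  solution c=0 in which the network would always be handed the answer.

Lowering c makes a hinted misclassified record cheaper under Lt but more
expensive under lambda*Lc; that trade-off is what turns c into a usable
out-of-distribution score at test time.

All functions here are pure numpy and dtype-preserving; the trainer consumes
:func:`total_loss_grads` for the analytic gradients.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class LossError(ValueError):
    pass


@dataclasses.dataclass
class LossConfig:
    gamma: float = 2.0
    lam: float = 0.1
    hint_fraction: float = 0.5
    eps: float = 1e-12
    symmetric_gamma: bool = False

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.lam < 0:
            raise LossError("gamma and lam must be non-negative")
        if not (0.0 <= self.hint_fraction <= 1.0):
            raise LossError("hint_fraction must lie in [0, 1]")


def _check_one_hot(y: np.ndarray) -> None:
    if not (np.all((y == 0) | (y == 1)) and np.all(y.sum(axis=-1) == 1)):
        raise LossError("y must be one-hot")


def hinted_probs(p: np.ndarray, c, y: np.ndarray) -> np.ndarray:
    """p_hat = c*p + (1-c)*y, broadcast over a batch or a single vector."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_one_hot(y)
    c = np.asarray(c, dtype=float)
    if p.ndim == 2 and c.ndim == 1:
        c = c[:, None]
    return c * p + (1.0 - c) * y


def focal_loss(
    p_hat: np.ndarray,
    y: np.ndarray,
    gamma: float = 2.0,
    symmetric_gamma: bool = False,
    eps: float = 1e-12,
):
    """Per-record focal loss Lt over class probabilities p_hat.

    Accepts a single probability vector or a (batch, M) array; returns a
    scalar or a (batch,) vector accordingly.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(p_hat < -eps) or np.any(p_hat > 1 + eps):
        raise LossError("p_hat entries outside [0, 1]")
    ph = np.clip(p_hat, eps, 1.0 - eps)
    pos = y * (1.0 - ph) ** gamma * np.log(ph)
    neg_weight = ph**gamma if symmetric_gamma else ph
    neg = (1.0 - y) * neg_weight * np.log(1.0 - ph)
    return -(pos + neg).sum(axis=-1)


def confidence_loss(c, eps: float = 1e-12):
    """Lc = -log(c) (natural log), floored at eps."""
    return -np.log(np.clip(np.asarray(c, dtype=float), eps, None))


def select_hinted(n: int, hint_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask choosing round(hint_fraction*n) random batch members."""
    n_hint = int(round(hint_fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:n_hint]] = True
    return mask


def total_loss(
    p: np.ndarray,
    c: np.ndarray,
    y: np.ndarray,
    cfg: LossConfig | None = None,
    rng: np.random.Generator | None = None,
    hint_mask: np.ndarray | None = None,
) -> float:
    """Batch objective L = mean(Lt) + lam * mean(Lc).

    The hinted subset is given either explicitly (``hint_mask``) or drawn from
    ``rng`` with exactly round(hint_fraction * n) members.
    """
    cfg = cfg or LossConfig()
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.ndim != 2 or p.shape[0] == 0:
        raise LossError("expected a non-empty (batch, M) probability array")
    _check_one_hot(y)
    if hint_mask is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        hint_mask = select_hinted(p.shape[0], cfg.hint_fraction, rng)
    ph = np.where(hint_mask[:, None], hinted_probs(p, c, y), p)
    lt = focal_loss(ph, y, cfg.gamma, cfg.symmetric_gamma, cfg.eps)
    lc = confidence_loss(c, cfg.eps)
    return float(lt.mean() + cfg.lam * lc.mean())


def total_loss_grads(
    p: np.ndarray,
    c: np.ndarray,
    y: np.ndarray,
    cfg: LossConfig,
    hint_mask: np.ndarray,
):
    """Value and analytic gradients (dL/dp, dL/dc) of :func:`total_loss`.

    The eps clip on p_hat is treated as pass-through for the gradient; in
    practice probabilities sit strictly inside the simplex after a softmax.
    """
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    n = p.shape[0]
    eps, gamma = cfg.eps, cfg.gamma
    ph_raw = np.where(hint_mask[:, None], hinted_probs(p, c, y), p)
    ph = np.clip(ph_raw, eps, 1.0 - eps)
    one_m = 1.0 - ph
    log_ph = np.log(ph)
    log_1m = np.log(one_m)

    # dLt/dp_hat, elementwise (Lt already carries the leading minus sign)
    if gamma == 0:
        d_pos = -1.0 / ph
    else:
        d_pos = gamma * one_m ** (gamma - 1.0) * log_ph - one_m**gamma / ph
    if cfg.symmetric_gamma:
        if gamma == 0:
            d_neg = ph**gamma / one_m
        else:
            d_neg = ph**gamma / one_m - gamma * ph ** (gamma - 1.0) * log_1m
    else:
        d_neg = ph / one_m - log_1m
    dlt_dph = y * d_pos + (1.0 - y) * d_neg

    # chain through the hint: dph/dp = c (hinted) else 1; dph/dc = p - y
    scale = np.where(hint_mask[:, None], c[:, None], 1.0)
    g_p = dlt_dph * scale / n
    g_c = np.where(hint_mask, (dlt_dph * (p - y)).sum(axis=1), 0.0) / n
    g_c = g_c - cfg.lam / np.clip(c, eps, None) / n

    lt = focal_loss(ph_raw, y, gamma, cfg.symmetric_gamma, eps)
    lc = confidence_loss(c, eps)
    value = float(lt.mean() + cfg.lam * lc.mean())
    return value, g_p, g_c
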