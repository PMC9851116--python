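"""Confidence-hinted focal loss against hand values and scalar-loop oracles."""

import math

import numpy as np
import pytest

from fvepnet.loss import (
    LossConfig,
    LossError,
    confidence_loss,
    focal_loss,
    hinted_probs,
    select_hinted,
    total_loss,
    total_loss_grads,
)


def oracle_total_loss(p, c, y, cfg, mask):
    """Independent elementwise scalar-loop implementation of the objective."""
    n, m = p.shape
    lt_sum, lc_sum = 0.0, 0.0
    for b in range(n):
        lt = 0.0
        for i in range(m):
            ph = c[b] * p[b, i] + (1 - c[b]) * y[b, i] if mask[b] else p[b, i]
            ph = min(max(ph, cfg.eps), 1 - cfg.eps)
            pos = y[b, i] * (1 - ph) ** cfg.gamma * math.log(ph)
            w = ph**cfg.gamma if cfg.symmetric_gamma else ph
            neg = (1 - y[b, i]) * w * math.log(1 - ph)
            lt -= pos + neg
        lt_sum += lt
        lc_sum += -math.log(max(c[b], cfg.eps))
    return lt_sum / n + cfg.lam * lc_sum / n


def random_batch(rng, n=16, m=2):
    z = rng.normal(size=(n, m))
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    c = rng.uniform(0.01, 0.99, n)
    y = np.eye(m)[rng.integers(0, m, n)]
    return p, c, y


# ----------------------------------------------------------------- hinting


def test_hint_limits_and_hand_value():
    p = np.array([0.7, 0.3])
    y = np.array([1.0, 0.0])
    np.testing.assert_allclose(hinted_probs(p, 1.0, y), p)
    np.testing.assert_allclose(hinted_probs(p, 0.0, y), y)
    np.testing.assert_allclose(hinted_probs(p, 0.5, y), [0.85, 0.15])


def test_hint_output_stays_on_simplex(rng):
    for _ in range(50):
        p, c, y = random_batch(rng, 8)
        ph = hinted_probs(p, c, y)
        np.testing.assert_allclose(ph.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((ph >= 0) & (ph <= 1))


def test_hint_rejects_non_one_hot():
    with pytest.raises(LossError, match="one-hot"):
        hinted_probs(np.array([0.5, 0.5]), 0.5, np.array([0.5, 0.5]))


# ----------------------------------------------------------------- focal


def test_focal_zero_at_perfect_prediction():
    y = np.array([1.0, 0.0])
    assert focal_loss(y, y, gamma=2.0) == pytest.approx(0.0, abs=1e-9)


def test_focal_hand_value_gamma2():
    val = focal_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]), gamma=2.0)
    expected = -(0.25 * math.log(0.5) + 0.5 * math.log(0.5))
    assert val == pytest.approx(expected, abs=1e-12)


def test_focal_gamma0_symmetric_reduces_to_cross_entropy(rng):
    for _ in range(100):
        p, _, y = random_batch(rng, 1)
        val = focal_loss(p[0], y[0], gamma=0.0, symmetric_gamma=True)
        ce = -sum(
            y[0, i] * math.log(p[0, i]) + (1 - y[0, i]) * math.log(1 - p[0, i])
            for i in range(2)
        )
        assert val == pytest.approx(ce, abs=1e-10)


def test_focal_rejects_out_of_range():
    with pytest.raises(LossError):
        focal_loss(np.array([1.4, -0.4]), np.array([1.0, 0.0]))


# ----------------------------------------------------------------- confidence


def test_confidence_loss_values():
    assert confidence_loss(1.0) == pytest.approx(0.0)
    assert confidence_loss(math.exp(-1)) == pytest.approx(1.0, abs=1e-12)
    cs = np.linspace(0.01, 1.0, 50)
    ls = confidence_loss(cs)
    assert np.all(np.diff(ls) < 0)  # monotone decreasing in c


# ----------------------------------------------------------------- total


def test_total_loss_degenerate_is_plain_focal(rng):
    p, c, y = random_batch(rng)
    cfg = LossConfig(lam=0.0, hint_fraction=0.0)
    val = total_loss(p, c, y, cfg, rng=np.random.default_rng(0))
    assert val == pytest.approx(float(np.mean(focal_loss(p, y, cfg.gamma))), abs=1e-12)


def test_total_loss_full_confidence_zeroes_lc(rng):
    p, _, y = random_batch(rng)
    c = np.ones(len(p))
    mask = select_hinted(len(p), 0.5, np.random.default_rng(1))
    val = total_loss(p, c, y, LossConfig(), hint_mask=mask)
    assert val == pytest.approx(float(np.mean(focal_loss(p, y, 2.0))), abs=1e-12)


@pytest.mark.parametrize("sym", [False, True])
def test_total_loss_matches_scalar_oracle(sym):
    rng = np.random.default_rng(42)
    cfg = LossConfig(symmetric_gamma=sym)
    for _ in range(100):
        p, c, y = random_batch(rng)
        mask = select_hinted(16, cfg.hint_fraction, rng)
        assert total_loss(p, c, y, cfg, hint_mask=mask) == pytest.approx(
            oracle_total_loss(p, c, y, cfg, mask), abs=1e-10
        )


def test_total_loss_nonnegative(rng):
    for _ in range(50):
        p, c, y = random_batch(rng)
        mask = select_hinted(16, 0.5, rng)
        assert total_loss(p, c, y, LossConfig(), hint_mask=mask) >= 0.0


def test_total_loss_empty_batch_error():
    with pytest.raises(LossError):
        total_loss(np.zeros((0, 2)), np.zeros(0), np.zeros((0, 2)), LossConfig())


def test_hint_mask_size_is_rounded_fraction(rng):
    assert select_hinted(16, 0.5, rng).sum() == 8
    assert select_hinted(10, 0.25, rng).sum() == round(2.5)
    assert select_hinted(7, 1.0, rng).sum() == 7
    assert select_hinted(7, 0.0, rng).sum() == 0


def test_focal_monotone_decreasing_in_true_class_probability():
    y = np.array([1.0, 0.0])
    ps = np.linspace(0.01, 0.99, 97)
    vals = [focal_loss(np.array([p1, 1 - p1]), y, gamma=2.0) for p1 in ps]
    assert np.all(np.diff(vals) < 0)


def test_confidence_tradeoff_for_misclassified_record():
    """Lowering c pulls hinted p toward y (cheaper Lt) but raises lam*Lc: the
    tension that makes c informative at test time."""
    p = np.array([[0.2, 0.8]])  # true class 0 misclassified
    y = np.array([[1.0, 0.0]])
    cfg = LossConfig(lam=0.1)
    mask = np.array([True])
    cs = np.linspace(0.95, 0.05, 19)
    lts, lcs = [], []
    for c in cs:
        ph = hinted_probs(p[0], c, y[0])
        lts.append(float(focal_loss(ph, y[0], cfg.gamma)))
        lcs.append(cfg.lam * float(confidence_loss(c)))
    assert np.all(np.diff(lts) < 0)  # Lt strictly decreases as c drops
    assert np.all(np.diff(lcs) > 0)  # lam*Lc strictly increases as c drops


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    p1=st.floats(1e-6, 1.0 - 1e-6),
    c=st.floats(0.0, 1.0),
    cls=st.integers(0, 1),
    gamma=st.floats(0.0, 5.0),
)
def test_loss_terms_nonnegative_and_hint_on_simplex(p1, c, cls, gamma):
    """For any probability vector, confidence and class: hinted probabilities
    stay on the simplex and both loss terms are non-negative."""
    p = np.array([p1, 1.0 - p1])
    y = np.eye(2)[cls]
    ph = hinted_probs(p, c, y)
    assert ph.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all((ph >= -1e-12) & (ph <= 1 + 1e-12))
    assert focal_loss(ph, y, gamma) >= 0.0
    assert confidence_loss(max(c, 1e-12)) >= -1e-12


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    p, c, y = random_batch(rng, n=6)
    for sym in (False, True):
        cfg = LossConfig(symmetric_gamma=sym)
        mask = select_hinted(6, 0.5, np.random.default_rng(0))
        _, gp, gc = total_loss_grads(p, c, y, cfg, mask)
        eps = 1e-6
        for i in range(6):
            cp, cm = c.copy(), c.copy()
            cp[i] += eps
            cm[i] -= eps
            fd = (
                total_loss(p, cp, y, cfg, hint_mask=mask)
                - total_loss(p, cm, y, cfg, hint_mask=mask)
            ) / (2 * eps)
            assert gc[i] == pytest.approx(fd, abs=1e-7)
            for j in range(2):
                pp, pm = p.copy(), p.copy()
                pp[i, j] += eps
                pm[i, j] -= eps
                fd = (
                    total_loss(pp, c, y, cfg, hint_mask=mask)
                    - total_loss(pm, c, y, cfg, hint_mask=mask)
                ) / (2 * eps)
                assert gp[i, j] == pytest.approx(fd, abs=1e-7)
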