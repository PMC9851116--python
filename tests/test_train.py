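"""Splitting, pretraining and the training loop on small problems."""

import numpy as np
import pytest

from fvepnet.records import signals_matrix
from fvepnet.synth import WaveformParams, generate_dataset
from fvepnet.train import (
    ConvAutoencoder,
    SplitError,
    SplitSpec,
    TrainConfig,
    TrainingDivergedError,
    partition,
    predict,
    pretrain_autoencoder,
    split_by_patient,
    train,
)
from fvepnet.model import ModelConfig


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_dataset({"normal": 10, "rp": 10}, WaveformParams(), rng_seed=1)


def test_split_exact_patient_counts(tiny_dataset):
    split = split_by_patient(tiny_dataset, train_fraction=0.7, seed=0)
    train_recs, test_recs = partition(tiny_dataset, split)
    # 10 patients per class at 0.7 -> exactly 7 train patients per class
    assert len(split.train_patients) == 14
    assert len(train_recs) == 14 * 4
    assert len(test_recs) == 6 * 4


def test_split_deterministic(tiny_dataset):
    a = split_by_patient(tiny_dataset, seed=5)
    b = split_by_patient(tiny_dataset, seed=5)
    assert a.train_patients == b.train_patients
    assert a.test_patients == b.test_patients


def test_split_no_patient_leaks(tiny_dataset):
    for seed in range(25):
        split = split_by_patient(tiny_dataset, seed=seed)
        assert not (split.train_patients & split.test_patients)


def test_abnormal_pool_splits_30_70():
    recs = generate_dataset({"normal": 10, "abnormal": 10}, WaveformParams(), rng_seed=2)
    split = split_by_patient(recs, seed=3)
    abn_train = [p for p in split.train_patients if p.startswith("abnormal")]
    abn_test = [p for p in split.test_patients if p.startswith("abnormal")]
    assert (len(abn_train), len(abn_test)) == (3, 7)


def test_split_invalid_fraction():
    with pytest.raises(SplitError):
        split_by_patient([], train_fraction=1.5)


# ---------------------------------------------------------------- pretraining


def test_autoencoder_mirrors_local_branch_shapes():
    cfg = ModelConfig()
    ae = ConvAutoencoder(cfg, seed=0)
    weights = ae.encoder_weights()
    assert [w.shape for w, _ in weights] == [(5, 1, 64), (3, 64, 64), (3, 64, 64)]
    x = np.zeros((2, 320, 1), dtype=np.float32)
    assert ae.forward(x).shape == (2, 320, 1)  # decoder restores input length


def test_pretraining_reduces_reconstruction_mse():
    recs = generate_dataset({"unlabelled": 25}, WaveformParams(), rng_seed=4)
    sig = signals_matrix(recs)  # 100 sweeps
    res = pretrain_autoencoder(sig, epochs=3, seed=0)
    assert res.mse_history[-1] < res.mse_initial


def test_pretraining_deterministic():
    recs = generate_dataset({"unlabelled": 10}, WaveformParams(), rng_seed=4)
    sig = signals_matrix(recs)
    r1 = pretrain_autoencoder(sig, epochs=2, seed=9)
    r2 = pretrain_autoencoder(sig, epochs=2, seed=9)
    for (w1, b1), (w2, b2) in zip(r1.encoder_weights, r2.encoder_weights):
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(b1, b2)


def test_pretrain_empty_pool_error():
    with pytest.raises(ValueError, match="empty"):
        pretrain_autoencoder(np.zeros((0, 320)))


# ---------------------------------------------------------------- training


def test_train_smoke_and_selection_rule(tiny_dataset):
    split = split_by_patient(tiny_dataset, seed=0)
    cfg = TrainConfig(epochs=3, batch_size=32, seed=0)
    res = train(tiny_dataset, split, cfg)
    assert len(res.log) == 3
    losses = [e["loss"] for e in res.log]
    assert res.best_epoch == int(np.argmin(losses)) + 1
    assert res.log[res.best_epoch - 1]["loss"] <= res.log[0]["loss"]


def test_pretrained_branch_gets_low_learning_rate(tiny_dataset):
    split = split_by_patient(tiny_dataset, seed=0)
    pool = signals_matrix([r for r in tiny_dataset])
    pre = pretrain_autoencoder(pool, epochs=1, seed=0)
    cfg = TrainConfig(epochs=1, batch_size=32, seed=0)

    # optimizer-state inspection: the local group must carry lr 0.001
    from fvepnet import train as train_mod
    from fvepnet._nn import SGD

    captured = {}
    orig_init = SGD.__init__

    def spy(self, params, lr, **kw):
        orig_init(self, params, lr, **kw)
        captured["lr"] = dict(self.lr) if isinstance(lr, dict) else lr
        captured["groups"] = {p.group for p in params}

    SGD.__init__ = spy
    try:
        train_mod.train(tiny_dataset, split, cfg, pretrained=pre)
    finally:
        SGD.__init__ = orig_init
    assert captured["lr"]["local"] == pytest.approx(0.001)
    assert captured["lr"]["rest"] == pytest.approx(0.01)
    assert {"local", "rest"} <= captured["groups"]


def test_training_with_and_without_pretraining_complete(tiny_dataset):
    split = split_by_patient(tiny_dataset, seed=1)
    pre = pretrain_autoencoder(signals_matrix(tiny_dataset), epochs=1, seed=1)
    cfg = TrainConfig(epochs=2, batch_size=32, seed=1)
    r_scratch = train(tiny_dataset, split, cfg)
    r_pre = train(tiny_dataset, split, cfg, pretrained=pre)
    assert len(r_scratch.log) == len(r_pre.log) == 2


def test_leakage_guard_trips_on_corrupt_split(tiny_dataset):
    split = split_by_patient(tiny_dataset, seed=0)
    some_test = next(iter(split.test_patients))
    corrupt = SplitSpec(
        train_patients=split.train_patients | {some_test},
        test_patients=split.test_patients,
        fractions=split.fractions,
        seed=0,
    )
    with pytest.raises(SplitError, match="leak"):
        train(tiny_dataset, corrupt, TrainConfig(epochs=1, batch_size=16, seed=0))


def test_separable_data_reaches_high_training_accuracy():
    """Noiseless, strongly separated classes must be fit almost perfectly."""
    params = WaveformParams(
        noise_std=0.05, drift_amplitude=0.0, baseline_offset_std=0.0, late_wave_std=0.0,
        rp_p2_attenuation=0.3,
        latency_jitter_ms=1.0, amplitude_scale_sigma=0.05, component_scale_sigma=0.02,
    )
    recs = generate_dataset({"normal": 15, "rp": 15}, params, rng_seed=6)
    split = split_by_patient(recs, seed=6)
    res = train(recs, split, TrainConfig(epochs=15, batch_size=32, seed=6))
    assert res.log[-1]["accuracy"] >= 0.99


def test_train_determinism(tiny_dataset):
    split = split_by_patient(tiny_dataset, seed=2)
    cfg = TrainConfig(epochs=2, batch_size=32, seed=2)
    r1 = train(tiny_dataset, split, cfg)
    r2 = train(tiny_dataset, split, cfg)
    p1, c1, _ = predict(r1.model, tiny_dataset[:8])
    p2, c2, _ = predict(r2.model, tiny_dataset[:8])
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(c1, c2)
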