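"""Patient-grouped splitting, autoencoder pretraining, and the training loop.

Splitting is done at the *patient* level: all four sweeps of a patient land on
the same side, so a model never sees a test patient's morphology during
training (the leakage guard in the batch loop enforces this at every step).
Normal and RP patients split 70/30 train/test; the abnormal
(out-of-distribution) pool splits 30/70, reflecting that OOD examples are
scarce at training time.

Pretraining: a convolutional autoencoder whose encoder is exactly the local
branch (conv 5/3/3 x 64 with max-pools) and whose decoder mirrors it with
nearest-neighbour upsampling and transposed convolutions, trained on
reconstruction MSE over an unlabelled pool.  The encoder weights are then
loaded into the network's local branch, which is finetuned at a 10x lower
learning rate (0.001) than the rest of the network (0.01).

Optimisation is minibatch SGD with momentum 0.9 (Adam available), batch 128,
50 epochs; the snapshot with the lowest epoch-mean training loss is returned.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import Adam, Conv1D, ConvTranspose1D, MaxPool1D, ReLU, SGD, Sequential, Upsample1D
from .features import P2_WINDOW_MS, manual_feature_matrix
from .loss import LossConfig, select_hinted, total_loss_grads
from .model import FvepNet, ModelConfig, build
from .records import FvepRecord, signals_matrix

CLASS_ORDER = ("normal", "rp")


class SplitError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclasses.dataclass
class SplitSpec:
    train_patients: set
    test_patients: set
    fractions: dict
    seed: int

    def side(self, patient_id: str) -> str:
        if patient_id in self.train_patients:
            return "train"
        if patient_id in self.test_patients:
            return "test"
        raise SplitError(f"patient {patient_id!r} not in this split")


@dataclasses.dataclass
class TrainConfig:
    lr_main: float = 0.01
    lr_local_pretrained: float = 0.001
    batch_size: int = 128
    epochs: int = 50
    seed: int = 0
    momentum: float = 0.9
    optimizer: str = "sgd"  # or "adam"
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    p2_window_ms: tuple = P2_WINDOW_MS
    select_by: str = "train_loss"
    abnormal_conf_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.lr_main <= 0 or self.lr_local_pretrained <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def split_by_patient(
    records: Sequence[FvepRecord],
    train_fraction: float = 0.70,
    abnormal_train_fraction: float = 0.30,
    seed: int = 0,
) -> SplitSpec:
    """Randomly assign patients (not records) to train/test per class.

    Normal/RP/unlabelled classes use ``train_fraction`` for training; the
    abnormal pool uses ``abnormal_train_fraction`` (default 30% train).
    Patient counts round to the nearest integer, so 10 patients at 0.7 give
    exactly 7 training patients.
    """
    if not (0.0 < train_fraction < 1.0) or not (0.0 < abnormal_train_fraction < 1.0):
        raise SplitError("fractions must lie strictly inside (0, 1)")
    by_class: dict = {}
    for r in records:
        by_class.setdefault(r.label, {}).setdefault(r.patient_id, 0)
        by_class[r.label][r.patient_id] += 1
    rng = np.random.default_rng(seed)
    train, test = set(), set()
    for label in sorted(by_class):
        pids = sorted(by_class[label])
        frac = abnormal_train_fraction if label == "abnormal" else train_fraction
        n_train = int(np.floor(frac * len(pids) + 0.5))
        order = rng.permutation(len(pids))
        chosen = {pids[i] for i in order[:n_train]}
        if n_train == 0 or n_train == len(pids):
            warnings.warn(f"class {label!r} has zero patients on one split side", stacklevel=2)
        train |= chosen
        test |= set(pids) - chosen
    return SplitSpec(
        train_patients=train,
        test_patients=test,
        fractions={"default": train_fraction, "abnormal": abnormal_train_fraction},
        seed=seed,
    )


def partition(records: Sequence[FvepRecord], split: SplitSpec):
    tr = [r for r in records if r.patient_id in split.train_patients]
    te = [r for r in records if r.patient_id in split.test_patients]
    return tr, te


# ---------------------------------------------------------------------------
# autoencoder pretraining


class ConvAutoencoder:
    """Encoder = local branch layers; decoder mirrors them back to length T."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        enc_layers, c_in = [], 1
        for i, (k, nf) in enumerate(zip(config.local_filter_sizes, config.local_filters)):
            enc_layers += [
                Conv1D(c_in, nf, k, rng, "local", f"enc{i}"),
                ReLU(),
                MaxPool1D(config.pool_size),
            ]
            c_in = nf
        self.encoder = Sequential(enc_layers)
        dec_layers = []
        specs = list(zip(config.local_filter_sizes, config.local_filters))
        for i, (k, nf) in enumerate(reversed(specs)):
            c_out = specs[len(specs) - 2 - i][1] if i < len(specs) - 1 else 1
            dec_layers += [Upsample1D(config.pool_size), ConvTranspose1D(nf, c_out, k, rng, "decoder", f"dec{i}")]
            if i < len(specs) - 1:
                dec_layers.append(ReLU())
        self.decoder = Sequential(dec_layers)
        self.config = config

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x))

    def backward(self, gy: np.ndarray) -> None:
        self.encoder.backward(self.decoder.backward(gy))

    def encoder_weights(self) -> list:
        return [
            (l.w.value.copy(), l.b.value.copy())
            for l in self.encoder.layers
            if isinstance(l, Conv1D)
        ]


@dataclasses.dataclass
class PretrainResult:
    encoder_weights: list
    mse_history: list
    mse_initial: float
    signal_mean: float
    signal_std: float


def pretrain_autoencoder(
    signals: np.ndarray,
    config: ModelConfig | None = None,
    epochs: int = 5,
    batch_size: int = 128,
    lr: float = 0.01,
    momentum: float = 0.9,
    seed: int = 0,
) -> PretrainResult:
    """Unsupervised reconstruction pretraining of the local branch.

    ``signals`` is the (n, T) unlabelled pool (typically training sweeps plus
    unlabelled sweeps).  Inputs are z-scored with pool statistics; MSE is
    measured on the standardized scale.
    """
    config = config or ModelConfig()
    x = np.asarray(signals, dtype=_nn.DTYPE)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("empty or malformed pretraining pool")
    mean, std = float(x.mean()), float(x.std() + 1e-8)
    x = (x - mean) / std
    ae = ConvAutoencoder(config, seed=seed)
    opt = SGD(ae.params, lr, momentum=momentum)
    rng = np.random.default_rng(seed)
    n = x.shape[0]

    def epoch_mse() -> float:
        tot = 0.0
        for s in range(0, n, batch_size):
            xb = x[s : s + batch_size, :, None]
            rec = ae.forward(xb)
            tot += float(((rec[:, :, 0] - xb[:, :, 0]) ** 2).sum())
        return tot / (n * x.shape[1])

    mse0 = epoch_mse()
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        tot = 0.0
        for s in range(0, n, batch_size):
            idx = order[s : s + batch_size]
            xb = x[idx][:, :, None]
            rec = ae.forward(xb)
            diff = rec - xb
            tot += float((diff[:, :, 0] ** 2).sum())
            opt.zero_grad()
            ae.backward(2.0 * diff / diff.size)
            opt.step()
        history.append(tot / (n * x.shape[1]))
    return PretrainResult(
        encoder_weights=ae.encoder_weights(),
        mse_history=history,
        mse_initial=mse0,
        signal_mean=mean,
        signal_std=std,
    )


# ---------------------------------------------------------------------------
# supervised training


def one_hot(labels: Sequence[str]) -> np.ndarray:
    idx = [CLASS_ORDER.index(l) for l in labels]
    return np.eye(len(CLASS_ORDER))[idx]


@dataclasses.dataclass
class TrainResult:
    model: FvepNet
    log: list  # per-epoch dicts: epoch, loss, accuracy
    best_epoch: int
    split: SplitSpec


def _check_leakage(batch: Sequence[FvepRecord], split: SplitSpec) -> None:
    bad = [r.patient_id for r in batch if r.patient_id in split.test_patients]
    if bad:
        raise SplitError(f"test patients leaked into a training batch: {bad[:5]}")


def train(
    records: Sequence[FvepRecord],
    split: SplitSpec,
    config: TrainConfig | None = None,
    pretrained: PretrainResult | list | None = None,
    abnormal_records: Sequence[FvepRecord] | None = None,
) -> TrainResult:
    """Two-phase training of the network on the split's training patients.

    When ``pretrained`` encoder weights are given, they are loaded into the
    local branch and that branch is optimised with ``lr_local_pretrained``
    (0.001) while every other parameter uses ``lr_main`` (0.01).

    ``abnormal_records`` (training-side OOD sweeps, when available) join the
    batches with a pure confidence objective ``-log(1 - c)``: the network is
    pushed to report low confidence on them, sharpening the confidence-based
    detector.  They carry no classification term.

    Raises :class:`TrainingDivergedError` on a non-finite loss.
    """
    config = config or TrainConfig()
    train_records = [
        r for r in records if r.patient_id in split.train_patients and r.label in CLASS_ORDER
    ]
    if not train_records:
        raise SplitError("no labelled training records in split")
    abnormal_records = [
        r for r in (abnormal_records or []) if r.patient_id in split.train_patients
    ]

    net = build(config.model, seed=config.seed)
    sig = signals_matrix(train_records)
    man = manual_feature_matrix(train_records, config.p2_window_ms)
    y = one_hot([r.label for r in train_records])
    net.set_normalization(sig, man)

    lr = {"rest": config.lr_main, "local": config.lr_main, "default": config.lr_main}
    if pretrained is not None:
        weights = pretrained.encoder_weights if isinstance(pretrained, PretrainResult) else pretrained
        net.load_local_branch(weights)
        lr["local"] = config.lr_local_pretrained
    opt_cls = {"sgd": SGD, "adam": Adam}[config.optimizer]
    if config.optimizer == "sgd":
        opt = opt_cls(net.params, lr, momentum=config.momentum)
    else:
        opt = opt_cls(net.params, lr)

    abn_sig = signals_matrix(abnormal_records) if abnormal_records else None
    abn_man = (
        manual_feature_matrix(abnormal_records, config.p2_window_ms) if abnormal_records else None
    )

    rng = np.random.default_rng(config.seed)
    n = len(train_records)
    log, best = [], (np.inf, 0, None)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        abn_order = rng.permutation(len(abnormal_records)) if abnormal_records else None
        ep_loss, ep_correct, ep_count = 0.0, 0, 0
        n_batches = int(np.ceil(n / config.batch_size))
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            batch = [train_records[i] for i in idx]
            _check_leakage(batch, split)
            out = net.forward(sig[idx], man[idx])
            mask = select_hinted(len(idx), config.loss.hint_fraction, rng)
            value, g_p, g_c = total_loss_grads(out.p, out.c, y[idx], config.loss, mask)
            if not np.isfinite(value):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(g_p, g_c)
            opt.step()
            ep_loss += value * len(idx)
            ep_correct += int((out.p.argmax(1) == y[idx].argmax(1)).sum())
            ep_count += len(idx)
            if abnormal_records:
                # low-confidence pressure on a batch of training-side OOD sweeps
                take = abn_order[
                    (b * config.batch_size) % len(abnormal_records) :
                ][: max(8, config.batch_size // 4)]
                if len(take) > 0:
                    out_a = net.forward(abn_sig[take], abn_man[take])
                    eps = config.loss.eps
                    ca = np.clip(out_a.c, eps, 1 - eps)
                    w = config.abnormal_conf_weight
                    g_ca = w / (1.0 - ca) / len(take)
                    opt.zero_grad()
                    net.backward(np.zeros_like(out_a.p), g_ca)
                    opt.step()
        ep_loss /= ep_count
        acc = ep_correct / ep_count
        log.append({"epoch": epoch, "loss": ep_loss, "accuracy": acc})
        if ep_loss < best[0]:
            best = (ep_loss, epoch, net.state_dict())
    if best[2] is not None:
        net.load_state_dict(best[2])
    return TrainResult(model=net, log=log, best_epoch=best[1], split=split)


def predict(net: FvepNet, records: Sequence[FvepRecord], p2_window_ms: tuple = P2_WINDOW_MS):
    """Forward pass over records; returns (p, c, penultimate)."""
    sig = signals_matrix(records)
    man = manual_feature_matrix(records, p2_window_ms)
    out = net.forward(sig, man)
    return out.p, out.c, out.penultimate
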