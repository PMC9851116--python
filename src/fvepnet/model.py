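"""The multi-branch confidence network for FVEP classification.

Three input branches are fused into a shared embedding with two heads:

* **global branch** — one 1-D convolution whose kernel spans the whole
  320-sample sweep (each of the 64 filters reduces the sweep to one scalar),
  capturing whole-waveform morphology;
* **local branch** — three (conv, ReLU, max-pool/2) stages with kernel sizes
  5/3/3 and 64 filters each, then flattened, capturing short-range deflection
  shapes; this is the branch that can be initialised from the convolutional
  autoencoder;
* **manual branch** — a 128-unit dense layer over the 7 hand-crafted features.

The concatenated branches pass through one fused dense layer (the
"penultimate" embedding used by the feature-space OOD detectors) and feed two
heads: a softmax over the M classes and a sigmoid confidence scalar
c in [0, 1].  Low c flags inputs the classifier should not be trusted on.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Conv1D, Dense, MaxPool1D, ReLU, Sequential, sigmoid, softmax
from .records import SWEEP_LENGTH


class ModelConfigError(ValueError):
    pass


@dataclasses.dataclass
class ModelConfig:
    input_length: int = SWEEP_LENGTH          # T
    n_classes: int = 2                        # M
    global_filters: int = 64
    local_filter_sizes: tuple = (5, 3, 3)
    local_filters: tuple = (64, 64, 64)
    pool_size: int = 2
    manual_features: int = 7
    manual_branch_units: int = 128
    fusion_units: int = 128

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ModelConfigError("n_classes must be >= 2")
        if self.input_length < max(self.local_filter_sizes):
            raise ModelConfigError("input shorter than the largest local kernel")
        if len(self.local_filter_sizes) != len(self.local_filters):
            raise ModelConfigError("local_filter_sizes and local_filters lengths differ")
        if min(
            (self.global_filters, self.manual_branch_units, self.fusion_units, self.pool_size)
            + tuple(self.local_filters)
        ) <= 0:
            raise ModelConfigError("all layer sizes must be positive")

    def local_output_length(self) -> int:
        """Length after the conv/pool stack (valid conv then floor-div pool)."""
        l = self.input_length
        for k in self.local_filter_sizes:
            l = (l - k + 1) // self.pool_size
        return l

    def local_output_dim(self) -> int:
        return self.local_output_length() * self.local_filters[-1]


@dataclasses.dataclass
class PredictionOutput:
    """Class probabilities p (sum to 1), confidence c in [0,1], and the
    fusion-layer embedding the OOD detectors operate on."""

    p: np.ndarray
    c: np.ndarray
    penultimate: np.ndarray


class FvepNet:
    """Trainable network; see module docstring for the architecture."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.global_conv = Conv1D(1, c.global_filters, c.input_length, rng, "rest", "global")
        self.global_relu = ReLU()
        layers = []
        c_in = 1
        for i, (k, nf) in enumerate(zip(c.local_filter_sizes, c.local_filters)):
            layers += [Conv1D(c_in, nf, k, rng, "local", f"local{i}"), ReLU(), MaxPool1D(c.pool_size)]
            c_in = nf
        self.local = Sequential(layers)
        self.manual_dense = Dense(c.manual_features, c.manual_branch_units, rng, "rest", "manual")
        self.manual_relu = ReLU()
        fused_in = c.global_filters + c.local_output_dim() + c.manual_branch_units
        self.fusion = Dense(fused_in, c.fusion_units, rng, "rest", "fusion")
        self.fusion_relu = ReLU()
        self.head_class = Dense(c.fusion_units, c.n_classes, rng, "rest", "head_class")
        self.head_conf = Dense(c.fusion_units, 1, rng, "rest", "head_conf")
        # input standardisation, set from the training split
        self.signal_mean, self.signal_std = 0.0, 1.0
        self.manual_mean = np.zeros(c.manual_features)
        self.manual_std = np.ones(c.manual_features)

    @property
    def params(self):
        return (
            self.global_conv.params
            + self.local.params
            + self.manual_dense.params
            + self.fusion.params
            + self.head_class.params
            + self.head_conf.params
        )

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def set_normalization(self, signals: np.ndarray, manual: np.ndarray) -> None:
        """Freeze z-score statistics from the training split."""
        self.signal_mean = float(signals.mean())
        self.signal_std = float(signals.std() + 1e-8)
        self.manual_mean = manual.mean(axis=0)
        self.manual_std = manual.std(axis=0) + 1e-8

    # ------------------------------------------------------------------
    def forward(self, signals: np.ndarray, manual: np.ndarray) -> PredictionOutput:
        """Batch forward pass (caches activations for a following backward)."""
        signals = np.asarray(signals, dtype=_nn.DTYPE)
        manual = np.asarray(manual, dtype=_nn.DTYPE)
        if signals.ndim != 2 or signals.shape[1] != self.config.input_length:
            raise ModelConfigError(
                f"signals must be (batch, {self.config.input_length}), got {signals.shape}"
            )
        if manual.shape != (signals.shape[0], self.config.manual_features):
            raise ModelConfigError(
                f"manual features must be (batch, {self.config.manual_features}), got {manual.shape}"
            )
        xs = (signals - self.signal_mean) / self.signal_std
        xm = (manual - self.manual_mean) / self.manual_std
        x3 = xs[:, :, None]
        g = self.global_relu.forward(self.global_conv.forward(x3))  # (b, 1, F)
        g = g.reshape(g.shape[0], -1)
        lo = self.local.forward(x3)
        self._local_out_shape = lo.shape
        lo = lo.reshape(lo.shape[0], -1)
        m = self.manual_relu.forward(self.manual_dense.forward(xm.astype(_nn.DTYPE)))
        fused_in = np.concatenate([g, lo, m], axis=1)
        self._split = (g.shape[1], g.shape[1] + lo.shape[1])
        emb = self.fusion_relu.forward(self.fusion.forward(fused_in))
        logits = self.head_class.forward(emb)
        u = self.head_conf.forward(emb)[:, 0]
        self._p = softmax(logits.astype(np.float64))
        self._c = sigmoid(u.astype(np.float64))
        return PredictionOutput(p=self._p, c=self._c, penultimate=emb.astype(np.float64))

    def backward(self, g_p: np.ndarray, g_c: np.ndarray) -> None:
        """Backprop from gradients w.r.t. p (batch, M) and c (batch,)."""
        g_logits = _nn.softmax_backward(self._p, g_p)
        g_u = g_c * self._c * (1.0 - self._c)
        g_emb = self.head_class.backward(g_logits.astype(_nn.DTYPE))
        g_emb = g_emb + self.head_conf.backward(g_u[:, None].astype(_nn.DTYPE))
        g_fused = self.fusion.backward(self.fusion_relu.backward(g_emb))
        s1, s2 = self._split
        g_g, g_lo, g_m = g_fused[:, :s1], g_fused[:, s1:s2], g_fused[:, s2:]
        self.global_conv.backward(self.global_relu.backward(g_g[:, None, :]))
        self.local.backward(g_lo.reshape(self._local_out_shape))
        self.manual_dense.backward(self.manual_relu.backward(g_m))

    # ------------------------------------------------------------------
    def load_local_branch(self, weights: list) -> None:
        """Copy pretrained (conv weight, bias) pairs into the local branch."""
        convs = [l for l in self.local.layers if isinstance(l, Conv1D)]
        if len(weights) != len(convs):
            raise ModelConfigError(
                f"expected {len(convs)} pretrained conv layers, got {len(weights)}"
            )
        for conv, (w, b) in zip(convs, weights):
            if conv.w.value.shape != w.shape or conv.b.value.shape != b.shape:
                raise ModelConfigError(
                    f"pretrained shape {w.shape} does not match branch shape {conv.w.value.shape}"
                )
            conv.w.value = w.astype(_nn.DTYPE).copy()
            conv.b.value = b.astype(_nn.DTYPE).copy()

    def local_branch_weights(self) -> list:
        return [
            (l.w.value.copy(), l.b.value.copy())
            for l in self.local.layers
            if isinstance(l, Conv1D)
        ]

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        d = {p.name: p.value.copy() for p in self.params}
        d["_norm/signal"] = np.array([self.signal_mean, self.signal_std])
        d["_norm/manual_mean"] = self.manual_mean.copy()
        d["_norm/manual_std"] = self.manual_std.copy()
        return d

    def load_state_dict(self, d: dict) -> None:
        for p in self.params:
            p.value = np.asarray(d[p.name], dtype=_nn.DTYPE).copy()
        self.signal_mean, self.signal_std = (float(v) for v in d["_norm/signal"])
        self.manual_mean = np.asarray(d["_norm/manual_mean"], dtype=float)
        self.manual_std = np.asarray(d["_norm/manual_std"], dtype=float)

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=2)
        )

    @classmethod
    def load(cls, path) -> "FvepNet":
        path = Path(path)
        cfg_dict = json.loads(path.with_suffix(".json").read_text())
        for key in ("local_filter_sizes", "local_filters"):
            cfg_dict[key] = tuple(cfg_dict[key])
        net = cls(ModelConfig(**cfg_dict))
        with np.load(path.with_suffix(".npz")) as z:
            net.load_state_dict({k: z[k] for k in z.files})
        return net


def build(config: ModelConfig | None = None, seed: int = 0) -> FvepNet:
    """Construct a freshly initialised network."""
    return FvepNet(config or ModelConfig(), seed=seed)
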