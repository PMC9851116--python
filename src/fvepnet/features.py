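"""Feature engineering: per-sweep descriptors, filtering, selection.

Three stages mirror the usual time-series feature-engineering pipeline:

1. :func:`extract_features` — a representative battery of temporal,
   statistical and spectral descriptors per sweep (plus patient age);
2. :func:`variance_filter` — drop (near-)constant columns;
3. :func:`pearson_select` — keep columns whose Pearson correlation with the
   binary class label clears a threshold.

:func:`manual_features` is the fixed 7-element vector fed to the network's
manual-feature branch: peak-to-peak amplitude (clinically the most
discriminative descriptor for RP, whose hallmark is a damped P2), the P2
window maximum and its latency, two dispersion summaries, roughness, and age.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .records import PRE_TRIGGER, SAMPLING_RATE, SWEEP_LENGTH, FvepRecord

#: default P2 search window, ms post-trigger
P2_WINDOW_MS = (100.0, 180.0)

MANUAL_FEATURE_NAMES = (
    "peak_to_peak",
    "p2_max",
    "p2_latency_ms",
    "std",
    "median",
    "mean_abs_diff",
    "age",
)


class FeatureError(ValueError):
    """Raised for malformed inputs to the feature pipeline."""


@dataclasses.dataclass
class FeatureTable:
    """n_records x n_features matrix with named, provenance-tagged columns."""

    values: np.ndarray
    feature_names: list
    provenance: dict  # name -> temporal | statistical | spectral | meta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: dict | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        names = list(df.columns)
        return cls(df.to_numpy(dtype=float), names, provenance or {n: "unknown" for n in names})


# --------------------------------------------------------------------------
# individual descriptors

def lag1_autocorrelation(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    v = np.var(x)
    if v == 0:
        return 0.0
    xc = x - x.mean()
    return float(np.dot(xc[:-1], xc[1:]) / (len(x) * v))

def mean_abs_diff(x: np.ndarray) -> float:
    return float(np.mean(np.abs(np.diff(x))))

def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r) with r = r_frac * std; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_frac * sd
    n = len(x)

    def _count(mm: int) -> int:
        # Chebyshev-distance template matches, self-matches excluded
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        matches = (d <= r).sum() - len(templ)  # remove diagonal
        return int(matches)

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float(np.log(n - m) + np.log(n - m - 1))  # conventional cap
    return float(-np.log(a / b))

def spectral_centroid(x: np.ndarray, fs: float = SAMPLING_RATE) -> float:
    mag = np.abs(np.fft.rfft(x - np.mean(x)))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    s = mag.sum()
    return float((freqs * mag).sum() / s) if s > 0 else 0.0

def fft_mean_coefficient(x: np.ndarray) -> float:
    return float(np.mean(np.abs(np.fft.rfft(x))))

def total_band_power(x: np.ndarray) -> float:
    xc = x - np.mean(x)
    return float(np.sum(xc**2) / len(x))

def wavelet_energies(x: np.ndarray, wavelet: str = "db4", level: int = 3) -> np.ndarray:
    """Energy of the three detail bands of a level-3 DWT."""
    coeffs = pywt.wavedec(x, wavelet, level=level)
    return np.array([float(np.sum(c**2)) for c in coeffs[1:]])  # d3, d2, d1 order


# --------------------------------------------------------------------------
# pipeline stages

def extract_features(records: Sequence[FvepRecord]) -> FeatureTable:
    """Per-record feature battery across temporal/statistical/spectral/meta."""
    rows, names, prov = [], None, {}
    for rec in records:
        x = np.asarray(rec.signal, dtype=float)
        if x.shape[0] != SWEEP_LENGTH:
            raise FeatureError(
                f"record {rec.patient_id}/{rec.eye}/{rec.repeat_index}: "
                f"expected {SWEEP_LENGTH} samples, got {x.shape[0]}"
            )
        hist, _ = np.histogram(x, bins=10)
        we = wavelet_energies(x)
        feats = {
            # temporal
            "lag1_autocorr": (lag1_autocorrelation(x), "temporal"),
            "mean_abs_diff": (mean_abs_diff(x), "temporal"),
            "sample_entropy": (sample_entropy(x), "temporal"),
            # statistical
            "max": (float(np.max(x)), "statistical"),
            "min": (float(np.min(x)), "statistical"),
            "median": (float(np.median(x)), "statistical"),
            "mean": (float(np.mean(x)), "statistical"),
            "std": (float(np.std(x)), "statistical"),
            "iqr": (float(np.percentile(x, 75) - np.percentile(x, 25)), "statistical"),
            "peak_to_peak": (float(np.max(x) - np.min(x)), "statistical"),
            # spectral
            "fft_mean_coeff": (fft_mean_coefficient(x), "spectral"),
            "spectral_centroid": (spectral_centroid(x), "spectral"),
            "total_power": (total_band_power(x), "spectral"),
            # meta
            "age": (float(rec.age), "meta"),
        }
        for i in range(10):
            feats[f"hist_bin_{i}"] = (float(hist[i]), "statistical")
        for i, e in enumerate(we, start=1):
            feats[f"dwt_energy_d{i}"] = (e, "spectral")
        if names is None:
            names = list(feats)
            prov = {k: v[1] for k, v in feats.items()}
        rows.append([feats[k][0] for k in names])
    values = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(values)):
        warnings.warn("non-finite feature values replaced by 0", stacklevel=2)
        values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureTable(values, names, prov)


def variance_filter(table: FeatureTable, threshold: float = 0.0) -> FeatureTable:
    """Drop columns with sample variance <= threshold (zero-variance default)."""
    if threshold < 0:
        raise FeatureError("variance threshold must be non-negative")
    var = np.var(table.values, axis=0)
    keep = var > threshold
    if not keep.any():
        raise FeatureError("variance filter removed every feature (degenerate dataset)")
    names = [n for n, k in zip(table.feature_names, keep) if k]
    return FeatureTable(table.values[:, keep], names, {n: table.provenance[n] for n in names})


def pearson_correlations(table: FeatureTable, labels: Sequence[int]) -> np.ndarray:
    """Pearson r of each column with the binary labels; 0 for constant columns."""
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != table.values.shape[0]:
        raise FeatureError("labels length does not match table rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise FeatureError("labels must be binary {0,1}")
    if np.all(y == y[0]):
        raise FeatureError("labels are all identical: correlation undefined")
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    xc = table.values - table.values.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2, axis=0))
    r = np.zeros(table.values.shape[1])
    nz = sx > 0
    r[nz] = (xc[:, nz] * yc[:, None]).sum(axis=0) / (sx[nz] * sy)
    return r


def pearson_select(table: FeatureTable, labels: Sequence[int], min_abs_r: float = 0.1) -> FeatureTable:
    """Keep columns with |Pearson r| >= min_abs_r against the labels."""
    if not (0.0 <= min_abs_r <= 1.0):
        raise FeatureError("min_abs_r must lie in [0, 1]")
    r = pearson_correlations(table, labels)
    keep = np.abs(r) >= min_abs_r
    names = [n for n, k in zip(table.feature_names, keep) if k]
    if not names:
        raise FeatureError("Pearson selection removed every feature")
    return FeatureTable(table.values[:, keep], names, {n: table.provenance[n] for n in names})


def manual_features(
    record: FvepRecord, p2_window_ms: tuple = P2_WINDOW_MS
) -> np.ndarray:
    """The fixed 7-element manual feature vector (order: MANUAL_FEATURE_NAMES).

    The P2 window is expressed in ms post-trigger; its argmax latency is
    returned in ms post-trigger (ties broken toward the earlier sample).
    """
    x = np.asarray(record.signal, dtype=float)
    lo = PRE_TRIGGER + int(round(p2_window_ms[0] * SAMPLING_RATE / 1000.0))
    hi = PRE_TRIGGER + int(round(p2_window_ms[1] * SAMPLING_RATE / 1000.0)) + 1
    window = x[lo:hi]
    p2_idx = int(np.argmax(window))
    p2_latency_ms = (lo + p2_idx - PRE_TRIGGER) * 1000.0 / SAMPLING_RATE
    return np.array(
        [
            float(np.max(x) - np.min(x)),
            float(window[p2_idx]),
            p2_latency_ms,
            float(np.std(x)),
            float(np.median(x)),
            mean_abs_diff(x),
            float(record.age),
        ]
    )


def manual_feature_matrix(records: Sequence[FvepRecord], p2_window_ms: tuple = P2_WINDOW_MS) -> np.ndarray:
    return np.stack([manual_features(r, p2_window_ms) for r in records])
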