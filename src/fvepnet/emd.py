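"""Empirical mode decomposition (EMD) and IMF-reconstruction denoising.

EMD adaptively splits a sweep into intrinsic mode functions (IMFs), ordered
from highest to lowest frequency, plus a monotone residual.  Acquisition noise
concentrates in the first IMFs and slow drift in the residual, so summing a
middle band of IMFs (3-5 by default) yields a denoised sweep.

Sifting details (conventions, since no single standard exists):
  * envelopes: cubic splines through local maxima / minima, with the extrema
    mirror-extended past both ends to tame spline boundary swings;
  * stop a sift when the normalised squared change between successive
    candidates drops below ``sd_threshold`` (0.2), capped at ``max_siftings``;
  * stop the decomposition when the remainder has fewer than 3 extrema, is
    monotone, or ``max_imf`` IMFs have been extracted (default 10, the dyadic
    filter-bank count expected for a 320-sample white-noise input).

The residual is computed as ``signal - sum(imfs)``, so the completeness
identity holds to floating-point round-off by construction.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .records import SWEEP_LENGTH


class EmdIndexError(ValueError):
    """Raised when a requested IMF index does not exist."""


@dataclasses.dataclass
class ImfSet:
    """Ordered IMFs (IMF1 = highest frequency) plus the residual trend."""

    imfs: list
    residual: np.ndarray
    original: np.ndarray

    def __len__(self) -> int:
        return len(self.imfs)


def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima (plateaus take the midpoint)."""
    d = np.diff(x)
    # collapse exact plateaus so sign changes are detectable
    s = np.sign(d)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    maxima, minima = [], []
    for i in range(1, len(s)):
        if s[i - 1] > 0 and s[i] < 0:
            maxima.append(i)
        elif s[i - 1] < 0 and s[i] > 0:
            minima.append(i)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema mirrored about both endpoints."""
    pos = idx.astype(float)
    val = x[idx]
    # mirror up to two extrema about each boundary
    k = min(2, len(idx))
    left_pos = -pos[:k][::-1]
    left_val = val[:k][::-1]
    right_pos = 2 * (n - 1) - pos[-k:][::-1]
    right_val = val[-k:][::-1]
    pos_ext = np.concatenate([left_pos, pos, right_pos])
    val_ext = np.concatenate([left_val, val, right_val])
    pos_ext, uniq = np.unique(pos_ext, return_index=True)
    val_ext = val_ext[uniq]
    if len(pos_ext) < 2:
        return np.full(n, val_ext[0])
    spline = CubicSpline(pos_ext, val_ext)
    return spline(np.arange(n))


def _sift(x: np.ndarray, sd_threshold: float, max_siftings: int) -> np.ndarray | None:
    """Extract one IMF from x; None when x has too few extrema to sift."""
    h = x.copy()
    n = len(x)
    for _ in range(max_siftings):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None
        upper = _mirrored_envelope(h, maxima, n)
        lower = _mirrored_envelope(h, minima, n)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = np.sum(h**2)
        sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_threshold:
            break
    return h


def decompose(
    signal: Sequence[float],
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
    max_imf: int = 10,
) -> ImfSet:
    """Decompose a sweep into IMFs plus a residual.

    A constant (or monotone) input has nothing to sift and returns zero IMFs
    with ``residual == signal``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    imfs: list[np.ndarray] = []
    remainder = x.copy()
    while len(imfs) < max_imf:
        maxima, minima = _local_extrema(remainder)
        if len(maxima) + len(minima) < 3:
            break
        imf = _sift(remainder, sd_threshold, max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        remainder = remainder - imf
    residual = x - (np.sum(imfs, axis=0) if imfs else np.zeros_like(x))
    return ImfSet(imfs=imfs, residual=residual, original=x)


def reconstruct(imf_set: ImfSet, indices: Iterable[int], include_residual: bool = False) -> np.ndarray:
    """Sum the selected 1-based IMFs (residual excluded unless requested)."""
    idx = sorted(set(int(i) for i in indices))
    out = np.zeros_like(imf_set.residual)
    for i in idx:
        if not (1 <= i <= len(imf_set.imfs)):
            raise EmdIndexError(
                f"IMF index {i} out of range: decomposition has {len(imf_set.imfs)} IMFs"
            )
        out = out + imf_set.imfs[i - 1]
    if include_residual:
        out = out + imf_set.residual
    return out


def denoise(signal: Sequence[float], indices: Iterable[int] = (3, 4, 5), **kwargs) -> np.ndarray:
    """Decompose and rebuild from the selected IMFs (default IMF3-IMF5).

    When the decomposition yields fewer IMFs than requested, the available
    selected IMFs are summed and a warning is emitted.  Not idempotent: EMD is
    adaptive, not a projection, so denoising a denoised sweep is undefined
    behaviour (documented, not asserted).
    """
    imf_set = decompose(signal, **kwargs)
    requested = sorted(set(int(i) for i in indices))
    available = [i for i in requested if i <= len(imf_set.imfs)]
    if len(available) < len(requested):
        warnings.warn(
            f"decomposition produced {len(imf_set.imfs)} IMFs; "
            f"dropping unavailable indices {sorted(set(requested) - set(available))}",
            stacklevel=2,
        )
    return reconstruct(imf_set, available)


def denoise_records(records, indices: Iterable[int] = (3, 4, 5)):
    """Apply :func:`denoise` to every record, preserving metadata."""
    out = []
    for r in records:
        out.append(dataclasses.replace(r, signal=denoise(r.signal, indices)))
    return out
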