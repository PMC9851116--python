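"""Core record types and dataset I/O.

An FVEP sweep is a fixed-length vector of 320 amplitude samples (microvolts):
20 ms of pre-trigger baseline followed by 300 ms post-trigger at a 1000 Hz
sampling rate.  Each record carries the patient id, eye, repeat index, age and
class label; every patient contributes exactly four sweeps (both eyes, twice).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sweep length in samples (20 ms pre-trigger + 300 ms post-trigger at 1 kHz)
SWEEP_LENGTH = 320
#: number of pre-trigger samples
PRE_TRIGGER = 20
#: sampling rate, Hz
SAMPLING_RATE = 1000.0

LABELS = ("normal", "rp", "abnormal", "unlabelled")
EYES = ("left", "right")

AGE_MIN = 4
AGE_MAX = 88


class RecordError(ValueError):
    """Raised for malformed FVEP records (wrong length, bad label, ...)."""


@dataclasses.dataclass(frozen=True)
class FvepRecord:
    """One 320-sample FVEP sweep plus its metadata."""

    signal: np.ndarray
    patient_id: str
    eye: str
    repeat_index: int
    age: int
    label: str

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 1 or sig.shape[0] != SWEEP_LENGTH:
            raise RecordError(
                f"record {self.patient_id}/{self.eye}/{self.repeat_index}: "
                f"signal must have length {SWEEP_LENGTH}, got shape {sig.shape}"
            )
        if not np.all(np.isfinite(sig)):
            raise RecordError(f"record {self.patient_id}: non-finite samples")
        object.__setattr__(self, "signal", sig)
        if self.eye not in EYES:
            raise RecordError(f"unknown eye {self.eye!r}")
        if self.repeat_index not in (1, 2):
            raise RecordError(f"repeat_index must be 1 or 2, got {self.repeat_index}")
        if self.label not in LABELS:
            raise RecordError(f"unknown label {self.label!r}")
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise RecordError(f"age {self.age} outside [{AGE_MIN}, {AGE_MAX}]")


def signals_matrix(records: Sequence[FvepRecord]) -> np.ndarray:
    """Stack record signals into an (n_records, 320) float array."""
    return np.stack([r.signal for r in records]).astype(float)


def labels_vector(records: Sequence[FvepRecord], positive: str = "normal") -> np.ndarray:
    """Binary label vector with 1 for ``positive`` class records."""
    return np.array([1 if r.label == positive else 0 for r in records], dtype=int)


def to_dataframe(records: Iterable[FvepRecord]) -> pd.DataFrame:
    """Long-format table: patient_id, eye, repeat, age, label, s0..s319."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "eye": r.eye,
            "repeat": r.repeat_index,
            "age": r.age,
            "label": r.label,
        }
        row.update({f"s{i}": v for i, v in enumerate(r.signal)})
        rows.append(row)
    return pd.DataFrame(rows)


def from_dataframe(df: pd.DataFrame) -> list[FvepRecord]:
    sig_cols = [f"s{i}" for i in range(SWEEP_LENGTH)]
    missing = [c for c in ("patient_id", "eye", "repeat", "age", "label") if c not in df]
    if missing or any(c not in df for c in sig_cols):
        raise RecordError(f"dataframe missing required columns (e.g. {missing or sig_cols[:3]})")
    out = []
    signals = df[sig_cols].to_numpy(dtype=float)
    for i, (_, row) in enumerate(df.iterrows()):
        out.append(
            FvepRecord(
                signal=signals[i],
                patient_id=str(row["patient_id"]),
                eye=str(row["eye"]),
                repeat_index=int(row["repeat"]),
                age=int(row["age"]),
                label=str(row["label"]),
            )
        )
    return out


def write_csv(records: Iterable[FvepRecord], path) -> None:
    to_dataframe(records).to_csv(path, index=False)


def read_csv(path) -> list[FvepRecord]:
    return from_dataframe(pd.read_csv(path))


def write_npz(records: Sequence[FvepRecord], path) -> None:
    """Compact binary container: one signal array plus metadata arrays."""
    np.savez_compressed(
        path,
        signals=signals_matrix(records),
        patient_id=np.array([r.patient_id for r in records]),
        eye=np.array([r.eye for r in records]),
        repeat=np.array([r.repeat_index for r in records]),
        age=np.array([r.age for r in records]),
        label=np.array([r.label for r in records]),
    )


def read_npz(path) -> list[FvepRecord]:
    with np.load(path, allow_pickle=False) as z:
        return [
            FvepRecord(
                signal=z["signals"][i],
                patient_id=str(z["patient_id"][i]),
                eye=str(z["eye"][i]),
                repeat_index=int(z["repeat"][i]),
                age=int(z["age"][i]),
                label=str(z["label"][i]),
            )
            for i in range(z["signals"].shape[0])
        ]
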