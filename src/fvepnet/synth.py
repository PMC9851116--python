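"""Synthetic FVEP generator.

Real flash-VEP sweeps are unavailable without a clinical collaboration, so
this module emulates their statistical structure: a normal sweep is a train of
six canonical deflections (N1, P1, N2, P2, N3, P3) riding on noise; a
retinitis-pigmentosa (RP) sweep shows a *reduced P2 amplitude at an unchanged
P2 peak time* — the clinical signature the classifier must learn; an
"abnormal" sweep is out-of-distribution relative to both classes (a global
latency shift, a near-flat response, or a noise-dominated trace).

Each deflection is a Gaussian bump (latency = mean, per-component width);
inter-individual variability is injected at the patient level (shared latency
jitter and amplitude scaling across a patient's four sweeps), measurement
noise at the record level.  All randomness flows from one integer seed through
per-patient / per-record ``numpy.random.SeedSequence`` substreams, so datasets
are reproducible record-for-record.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.signal import butter, filtfilt

from .records import (
    AGE_MAX,
    AGE_MIN,
    PRE_TRIGGER,
    SAMPLING_RATE,
    SWEEP_LENGTH,
    FvepRecord,
)

COMPONENTS = ("N1", "P1", "N2", "P2", "N3", "P3")

ABNORMAL_SUBTYPES = ("latency_shift", "flat", "noisy")


class SynthError(ValueError):
    """Raised for invalid generator parameters or class labels."""


def _default_latencies() -> dict:
    return {"N1": 45.0, "P1": 75.0, "N2": 105.0, "P2": 135.0, "N3": 180.0, "P3": 220.0}


def _default_amplitudes() -> dict:
    return {"N1": -3.0, "P1": 4.0, "N2": -5.0, "P2": 10.0, "N3": -6.0, "P3": 5.0}


def _default_widths() -> dict:
    return {"N1": 7.0, "P1": 8.0, "N2": 8.0, "P2": 9.0, "N3": 12.0, "P3": 14.0}


@dataclasses.dataclass
class WaveformParams:
    """Generative parameters for one synthetic sweep family.

    Latencies and widths are in ms post-trigger, amplitudes in microvolts.
    For the RP class the whole response is damped (``rp_other_attenuation``),
    with P2 attenuated most strongly (``rp_p2_attenuation``, the *total* P2
    factor) and every peak time left untouched — the clinical picture of a
    generalized retinal dysfunction whose hallmark is the damped P2.

    Record-level nuisance terms emulate what incomplete averaging leaves in a
    real sweep: white Gaussian noise (``noise_std``), a slow random-phase
    baseline oscillation (``drift_amplitude``), a DC baseline offset
    (``baseline_offset_std`` — the reason clinical VEP amplitudes are read
    peak-to-trough rather than from baseline), and a highly variable,
    label-independent late secondary wave beyond P3 (``late_wave_*``).
    ``bandpass`` optionally applies the 0.312–100 Hz acquisition filter to
    the white noise.
    """

    latencies_ms: Mapping[str, float] = dataclasses.field(default_factory=_default_latencies)
    amplitudes_uv: Mapping[str, float] = dataclasses.field(default_factory=_default_amplitudes)
    widths_ms: Mapping[str, float] = dataclasses.field(default_factory=_default_widths)
    noise_std: float = 1.0
    drift_amplitude: float = 0.5
    baseline_offset_std: float = 1.5
    late_wave_std: float = 2.0
    late_wave_latency_range: tuple = (245.0, 285.0)
    late_wave_width_ms: float = 22.0
    rp_p2_attenuation: float = 0.5
    rp_other_attenuation: float = 0.7
    bandpass: bool = False
    # patient-level variability (shared across a patient's 4 records)
    latency_jitter_ms: float = 3.0
    amplitude_scale_sigma: float = 0.15
    component_scale_sigma: float = 0.10
    # abnormal/OOD mixture
    abnormal_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"latency_shift": 1.0, "flat": 1.0, "noisy": 1.0}
    )
    latency_shift_range_ms: tuple = (30.0, 60.0)

    def __post_init__(self) -> None:
        lats = [self.latencies_ms[c] for c in COMPONENTS]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise SynthError(f"component latencies must be strictly increasing: {lats}")
        if not all(0.0 <= l <= 300.0 for l in lats):
            raise SynthError(f"latencies must lie within [0, 300] ms: {lats}")
        if not (0.0 < self.rp_p2_attenuation < 1.0):
            raise SynthError(f"rp_p2_attenuation must be in (0,1), got {self.rp_p2_attenuation}")
        if not (0.0 < self.rp_other_attenuation <= 1.0):
            raise SynthError(
                f"rp_other_attenuation must be in (0,1], got {self.rp_other_attenuation}"
            )
        if self.noise_std < 0:
            raise SynthError("noise_std must be non-negative")
        if min(self.latency_shift_range_ms) < 30.0:
            raise SynthError("abnormal latency shift must be at least 30 ms")


def _bump_train(latencies, amplitudes, widths) -> np.ndarray:
    """Sum of Gaussian deflections on the 320-sample grid (pre-trigger flat)."""
    t_ms = (np.arange(SWEEP_LENGTH) - PRE_TRIGGER) * 1000.0 / SAMPLING_RATE
    sig = np.zeros(SWEEP_LENGTH)
    for c in COMPONENTS:
        sig += amplitudes[c] * np.exp(-0.5 * ((t_ms - latencies[c]) / widths[c]) ** 2)
    return sig


def _noise(params: WaveformParams, rng: np.random.Generator, std_scale: float = 1.0) -> np.ndarray:
    n = rng.normal(0.0, params.noise_std * std_scale, SWEEP_LENGTH)
    if params.bandpass and params.noise_std > 0:
        b, a = butter(2, [0.312 / (SAMPLING_RATE / 2), 100.0 / (SAMPLING_RATE / 2)], "bandpass")
        n = filtfilt(b, a, n)
    if params.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 2.0)  # Hz, slow baseline wander
        t = np.arange(SWEEP_LENGTH) / SAMPLING_RATE
        n = n + params.drift_amplitude * std_scale * np.sin(2 * np.pi * freq * t + phase)
    if params.baseline_offset_std > 0:
        n = n + rng.normal(0.0, params.baseline_offset_std)
    if params.late_wave_std > 0:
        t_ms = (np.arange(SWEEP_LENGTH) - PRE_TRIGGER) * 1000.0 / SAMPLING_RATE
        amp = rng.normal(0.0, params.late_wave_std)
        lat = rng.uniform(*params.late_wave_latency_range)
        n = n + amp * np.exp(-0.5 * ((t_ms - lat) / params.late_wave_width_ms) ** 2)
    return n


def _clean_signal(label: str, params: WaveformParams, rng: np.random.Generator) -> np.ndarray:
    lats = dict(params.latencies_ms)
    amps = dict(params.amplitudes_uv)
    if label == "normal" or label == "unlabelled":
        return _bump_train(lats, amps, params.widths_ms)
    if label == "rp":
        # generalized retinal dysfunction: the whole response is damped, with
        # P2 attenuated most strongly; every peak time is left unchanged
        amps = {c: a * params.rp_other_attenuation for c, a in amps.items()}
        amps["P2"] = params.amplitudes_uv["P2"] * params.rp_p2_attenuation
        return _bump_train(lats, amps, params.widths_ms)
    if label == "abnormal":
        kinds = list(params.abnormal_weights)
        w = np.array([params.abnormal_weights[k] for k in kinds], dtype=float)
        kind = kinds[rng.choice(len(kinds), p=w / w.sum())]
        if kind == "latency_shift":
            shift = rng.uniform(*params.latency_shift_range_ms)
            lats = {c: min(l + shift, 299.0) for c, l in lats.items()}
            return _bump_train(lats, amps, params.widths_ms)
        if kind == "flat":
            amps = {c: a * 0.05 for c, a in amps.items()}
            return _bump_train(lats, amps, params.widths_ms)
        if kind == "noisy":
            amps = {c: a * 0.3 for c, a in amps.items()}
            base = _bump_train(lats, amps, params.widths_ms)
            return base + rng.normal(0.0, max(params.noise_std, 0.5) * 7.0, SWEEP_LENGTH)
        raise SynthError(f"unknown abnormal subtype {kind!r}")
    raise SynthError(f"unknown class label {label!r}")


def generate_record(
    class_label: str,
    params: WaveformParams | None = None,
    rng_seed: int = 0,
    *,
    patient_id: str = "p0",
    eye: str = "left",
    repeat_index: int = 1,
    age: int = 42,
) -> FvepRecord:
    """Generate a single synthetic sweep of the given class.

    The clean waveform is the Gaussian bump train for the class (RP sweeps get
    ``rp_p2_attenuation`` applied to P2 only); record-level noise and drift are
    added on top.  Deterministic for a fixed seed and parameters.
    """
    if class_label not in ("normal", "rp", "abnormal", "unlabelled"):
        raise SynthError(f"unknown class label {class_label!r}")
    params = params or WaveformParams()
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    sig = _clean_signal(class_label, params, rng) + _noise(params, rng)
    return FvepRecord(
        signal=sig,
        patient_id=patient_id,
        eye=eye,
        repeat_index=repeat_index,
        age=age,
        label=class_label,
    )


def _perturbed_params(params: WaveformParams, rng: np.random.Generator) -> WaveformParams:
    """Patient-level draw: shared latency jitter and amplitude scaling."""
    lats = dict(params.latencies_ms)
    amps = dict(params.amplitudes_uv)
    global_scale = np.exp(rng.normal(0.0, params.amplitude_scale_sigma))
    jitters = rng.normal(0.0, params.latency_jitter_ms, len(COMPONENTS))
    for i, c in enumerate(COMPONENTS):
        lats[c] = float(np.clip(lats[c] + jitters[i], 1.0, 299.0))
        amps[c] = amps[c] * global_scale * np.exp(rng.normal(0.0, params.component_scale_sigma))
    # jitter may not preserve strict ordering for extreme draws; re-sort latencies
    order = sorted(COMPONENTS, key=lambda c: lats[c])
    lats = {c: lats[o] for c, o in zip(COMPONENTS, order)}
    return dataclasses.replace(params, latencies_ms=lats, amplitudes_uv=amps)


def generate_dataset(
    n_patients_per_class: Mapping[str, int],
    params: WaveformParams | None = None,
    rng_seed: int = 0,
) -> list[FvepRecord]:
    """Generate a patient-structured dataset: 4 records per patient.

    Each patient gets an age drawn uniformly from [4, 88] and a patient-level
    perturbation of the waveform parameters; the four sweeps (2 eyes x 2
    repeats) then differ only by record-level noise.
    """
    params = params or WaveformParams()
    for label, n in n_patients_per_class.items():
        if label not in ("normal", "rp", "abnormal", "unlabelled"):
            raise SynthError(f"unknown class label {label!r}")
        if n < 0:
            raise SynthError(f"negative patient count for {label!r}")
    records: list[FvepRecord] = []
    pidx = 0
    for label in sorted(n_patients_per_class):
        for _ in range(n_patients_per_class[label]):
            pat_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, pidx]))
            age = int(pat_rng.integers(AGE_MIN, AGE_MAX + 1))
            pparams = _perturbed_params(params, pat_rng)
            pid = f"{label}-{pidx:05d}"
            for e_i, eye in enumerate(("left", "right")):
                for rep in (1, 2):
                    rec_rng = np.random.default_rng(
                        np.random.SeedSequence([rng_seed, pidx, e_i, rep])
                    )
                    sig = _clean_signal(label, pparams, rec_rng) + _noise(pparams, rec_rng)
                    records.append(
                        FvepRecord(
                            signal=sig,
                            patient_id=pid,
                            eye=eye,
                            repeat_index=rep,
                            age=age,
                            label=label,
                        )
                    )
            pidx += 1
    return records
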