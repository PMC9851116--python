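# Methods

## Problem and model

A flash visual evoked potential (FVEP) sweep is the averaged occipital
response to a brief flash: 320 samples at 1000 Hz (20 ms pre-trigger +
300 ms post-trigger), in microvolts, with six named deflections
(N1, P1, N2, P2, N3, P3). Retinitis pigmentosa (RP) presents as a *reduced
P2 amplitude at an unchanged P2 peak time*. The classifier must both separate
normal from RP sweeps and flag sweeps that belong to neither class
(out-of-distribution, OOD): grossly delayed, near-extinguished, or
noise-dominated responses.

The network has three input branches fused into a shared 128-unit embedding
with two heads:

* **global branch** — one 1-D convolution whose kernel spans the entire
  sweep (T = 320); each of the 64 filters reduces the sweep to a single
  scalar, so the branch scores whole-waveform templates;
* **local branch** — three stages of (valid conv k = 5/3/3, 64 filters,
  ReLU, max-pool 2), flattened (38 × 64 = 2432 values); this branch can be
  initialised from a convolutional autoencoder;
* **manual branch** — a 128-unit dense layer over 7 hand-crafted features
  (peak-to-peak amplitude, P2-window max and argmax latency, standard
  deviation, median, mean |first difference|, age).

Heads: softmax over M = 2 classes (p) and a sigmoid confidence scalar
c ∈ [0, 1]. The fusion embedding is also the feature space for the classical
novelty detectors.

### Loss

With y one-hot, a randomly chosen half of each batch is *hinted*:
p̂ = c·p + (1 − c)·y; the rest uses p̂ = p. The per-record objective is

    Lt = − Σ_i [ y_i (1 − p̂_i)^γ log p̂_i + (1 − y_i) p̂_i log(1 − p̂_i) ]
    Lc = − log c
    L  = mean(Lt) + λ · mean(Lc)

with γ = 2, λ = 0.1, natural logs, probabilities floored at 1e-12. The
negative-class term carries no γ exponent by default (the printed form of
the loss we implement); `symmetric_gamma=True` switches to the standard
focal form (1 − y)·p̂^γ·log(1 − p̂). Whether the missing exponent is a typo
in the source description is undecidable from the text, so both behaviours
ship and the printed form is the default. Lowering c makes a hinted
misclassified record cheaper under Lt and dearer under λLc; at test time
1 − c is therefore an OOD score.

When abnormal (OOD) training sweeps are available they join training with a
pure confidence penalty −w·log(1 − c) (w = 0.5) and no classification term:
the network learns to be *unconfident* on them. This is our reading of "the
anomalous training set is needed" for the confidence method; the mechanism
by which it enters training was not specified by the method's description.

## Training

Patient-grouped splitting: all four sweeps of a patient (2 eyes × 2 repeats)
land on one side. Normal/RP patients split 70/30 train/test; the abnormal
pool 30/70 (OOD examples are scarce at training time). Patient counts round
to nearest. A leakage guard in the batch loop raises if any test patient
reaches a gradient step.

Optimiser: minibatch SGD, momentum 0.9, batch 128, 50 epochs, lr 0.01;
with pretraining the local branch forms a second parameter group at lr
0.001. Gradients are clipped to global L2 norm 5 — the focal/confidence
objective has 1/p-scale spikes that otherwise saturate the softmax within
the first epoch. The epoch snapshot with the lowest *training* loss is
returned (a validation-loss switch exists but fidelity to the stated
selection rule is the default). Raw signals and manual features are z-scored
with training-split statistics. The network runs in float32; a fixed seed
makes runs bit-reproducible on one machine.

Pretraining: the autoencoder's encoder is exactly the local branch; the
decoder mirrors it with nearest-neighbour ×2 upsampling and transposed
convolutions (76→78→156→158→316→320), so input length is restored exactly.
Trained on reconstruction MSE over a z-scored unlabelled pool, 5 epochs.
The decoder architecture is unspecified in the source description; mirroring
is the convention we adopt.

## EMD denoising (optional preprocessing)

Standard sifting: cubic-spline envelopes through maxima/minima with the two
outermost extrema mirrored past each boundary; a sift stops when the
normalised squared change drops below 0.2 (max 50 sifts); decomposition
stops when the remainder has < 3 extrema or 10 IMFs (the dyadic filter-bank
count for 320 samples) are out. The residual is `signal − Σ IMFs`, so
completeness holds to round-off by construction. Denoising sums IMF3–IMF5
(1-based, residual excluded); if fewer IMFs exist, the available ones are
summed under a warning. EMD is adaptive, not a projection, so denoising is
*not* idempotent; it is a config flag (default off) in the training
pipeline, since the source describes it under acquisition rather than model
training.

## Feature engineering

`extract_features` computes a representative battery per domain — temporal
(lag-1 autocorrelation, mean |Δ|, sample entropy with m = 2, r = 0.2·sd),
statistical (max, min, median, mean, sd, IQR, 10-bin histogram,
peak-to-peak), spectral (FFT mean |coefficient|, spectral centroid, total
power, level-3 db4 DWT detail energies) plus age — not a full 60+ catalogue.
Selection is variance filtering (drop variance ≤ threshold, default 0) then
Pearson correlation against the binary label (keep |r| ≥ 0.1 by default;
zero-variance columns score 0). The identity of the original 7 selected
features is undocumented beyond peak-to-peak and age; our fixed default set
is a reconstruction and fully config-overridable. Selection and
standardisation statistics are frozen on the training split only.

## Synthetic data: what it emulates and what it does not

Each deflection is a Gaussian bump (latency = mean, per-component width);
defaults N1 45/P1 75/N2 105/P2 135/N3 180/P3 220 ms with amplitudes
−3/4/−5/10/−6/5 µV. Patient-level draws (shared by a patient's four sweeps):
age ~ U[4, 88], global amplitude scale (lognormal σ 0.15), per-component
scale (σ 0.10), latency jitter (σ 3 ms). Record-level nuisance: white noise
(σ 1 µV, optionally band-passed 0.312–100 Hz), slow baseline wander
(0.5 µV, 0.5–2 Hz), a DC baseline offset (σ 1.5 µV), and a variable
label-independent late wave beyond P3 (σ 2 µV at 245–285 ms). The RP class
damps the whole response (×0.7) with P2 damped most (×0.5 total) at
unchanged latencies — generalized retinal dysfunction with the damped P2 as
its hallmark. Abnormal/OOD sweeps mix three subtypes (equal weights):
≥ 30 ms global latency shift, near-flat response (×0.05), noise-dominated
trace.

Two design points deserve emphasis. The DC offset is why clinical VEP
amplitudes are read peak-to-trough: without it, an absolute P2-window
maximum would be unrealistically reliable. The variable late wave mirrors
the well-known inter-individual variability of late flash-VEP activity.
Together with the generalized RP damping they make peak-to-peak amplitude
the most label-correlated manual feature — the importance ranking the
generator is designed to emulate, verified across independent seeds rather
than tuned to any single one. All randomness flows from one seed through
per-patient/per-record `SeedSequence` substreams.

Limitations: no volume conduction or cortical source structure, no
age-dependent morphology, Gaussian bumps instead of real component shapes,
independent noise across a patient's sweeps. Passing tests show that the
method behaves as designed under these contrasts; they say nothing about
clinical accuracy on real recordings.

## Numerical and design choices

* Convolutions are stride-1 "valid"; the T×1 global kernel then yields
  exactly one value per filter. Flatten (not global-average-pool) after the
  local stack. Fusion width 128, matching the manual branch. No dropout or
  batch-norm in the main network.
* He-style uniform fan-in initialisation from the run seed.
* Hinting uses exactly round(hint_fraction·n) batch members; `hint_fraction=1`
  recovers always-hinted training.
* Softmax/sigmoid computed in float64 at the heads; analytic loss gradients
  verified against finite differences; the eps clip is treated as
  pass-through in gradients.
* OOD detectors: LOF (k = 20), one-class SVM (RBF, ν = 0.1), MCD (default
  support fraction, PCA-compressed to n/2 dimensions when the embedding
  cloud has n ≤ 2·dim points, since robust covariance is rank-deficient on
  128-dim ReLU-sparse embeddings). "Last fully connected layer" is read as
  the post-concatenation fusion embedding. Thresholds maximise F1 on
  training-side scores and are frozen before test metrics; OOD is the
  positive class for detection metrics, "normal" the positive class for
  classification (config-switchable).
* Standard benchmark sizes (60 normal + 60 RP + 40 abnormal patients,
  50 epochs) are the package's fixed study conditions for seeded end-to-end
  checks; the 5-seed learning check uses 100 + 100 patients.
* Degenerate inputs: constant sweeps yield zero IMFs and zero-variance
  features (replaced by 0 under a warning); argmax ties break to the first
  sample; all-identical labels or scores raise named errors.

## Known limitations

The clinical headline numbers of the original study are not reproducible
here — its dataset is available only on request — so all quantitative
results in this package are properties of the synthetic benchmark. The
confidence detector's advantage over entropy depends on abnormal training
exposure; without any abnormal training records the confidence branch is
trained by hinting alone and separates OOD less sharply. Training is
CPU-only and single-threaded by design of the implementation.
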