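# Methods

This note documents the models, parameter choices and numerical
conventions behind `mcgscreen`, and what its synthetic experiments do
and do not demonstrate about clinical data.

## Signal model and the synthetic cohort

The pipeline assumes a single-channel cardiac magnetometry recording:
quasi-periodic beats of roughly 800 ms, contaminated by baseline
wander, power-line interference and broadband noise, with a binary
subject label (healthy / ischemia).

The synthetic generator emulates exactly that structure.  One beat is a
sum of three Gaussian wavelets standing in for the P, QRS and T
complexes (centers 0.15 / 0.35 / 0.60 s, amplitudes 0.15 / 1.0 / 0.30,
widths 25 / 12 / 40 ms, in arbitrary field units).  The ischemic
template differs in three ways, chosen once as the package's study
conditions:

* an ST-level depression of −0.20 units applied between the QRS and T
  centers with 20 ms cosine ramps (band-limited, so it survives the
  0.5–100 Hz bandpass);
* a flattened, broadened T analogue (amplitude 0.18, width 60 ms);
* chaotic beat-to-beat amplitude modulation: each wavelet amplitude is
  scaled by `1 + c·(2u_k − 1)` where `u_k` iterates the logistic map
  `u ← 4u(1−u)` (its fully chaotic regime) and `c = 0.3`.  This is what
  disrupts the recurrence-plot texture for the ischemic class.

Subjects get a single morphology jitter draw (5% relative), so cycles
within a subject correlate — the property that makes subject-level
splitting meaningful — plus 2% per-beat cycle-length jitter.  Noise
defaults: white SD 0.02, 50 Hz tone amplitude 0.05, 0.2 Hz wander
amplitude 0.30.  Default sampling rate 1000 Hz, cycle length 0.8 s.

What this generator does *not* emulate: realistic electromagnetic
forward fields, multi-channel spatial structure, heart-rate dynamics
(HRV beyond white RR jitter), arrhythmia, electrode/sensor artifacts,
or the continuum of disease severity.  The two classes are cleanly
separable by construction, so a high synthetic AUC demonstrates that
the pipeline's plumbing—encoding, training, fusion, evaluation—is
correct and leak-free, not that the method reaches any particular
clinical accuracy.

## Preprocessing

Fourth-order Butterworth bandpass 0.5–100 Hz, then a second-order IIR
notch at 50 Hz (Q = 30), both applied forward–backward.  Zero-phase
filtering is chosen because processing is offline per recording and
phase distortion would warp the ST-segment geometry that GASF encodes.
The 0.5 Hz edge rings for several seconds; tests trim 5 s before
measuring filter gains.

Z-score normalization uses the population (ddof = 0) standard
deviation, treating the recording as the population; it stabilizes
amplitude at recording level.  Min–max scaling to [0, 1] happens per
cycle and is the direct encoder input.  Constant inputs raise a
degenerate-input error rather than returning NaNs.

Beat detection is a Pan-Tompkins-style chain adapted to magnetic
signals by rectifying first (field polarity depends on sensor
orientation): |x| → 5–15 Hz bandpass → derivative → squaring → 150 ms
moving-window integration → adaptive threshold at 0.4× the running mean
of the last 8 accepted integrated peaks, 200 ms refractory, with each
detection refined to the local maximum of the rectified band signal.
All constants are keyword-configurable.  Strong chaotic amplitude
modulation can push individual beats below the adaptive threshold;
missed beats cost cycles but never corrupt the ones that are kept.

Each detected beat is cut to [peak − 0.3·RRmed, peak + 0.5·RRmed]
(median RR), covering the P-through-T span, linearly resampled to 224
samples (the CNN input side) and min–max scaled.  Degenerate or
out-of-bounds windows are dropped.

Splitting is stratified at subject level: per class, shuffle with the
seed, floor(0.2·n) subjects to test, floor(0.1·n) to val, remainder to
train.  The floor rule makes a 1135 + 983 cohort yield a 423-subject
test partition (227 + 196).

## Embedding and encoders

`delay_embed` is exact index arithmetic.  The delay selector computes
histogram mutual information (16 equal-width bins by default) over lags
and returns the first local minimum; a series whose lag-1 MI is already
at the chance level of the estimator (Miller–Madow bias, `(B−1)²/2n`)
returns τ = 1 immediately, which is what white noise produces.  A
caveat found during development: for a *noiseless* deterministic
sinusoid the binned MI has a broad flat valley (the underlying MI is
lag-independent), so the quarter-period result of the autocorrelation
analogy emerges only once a little noise breaks determinism; tests use
σ = 0.1 noisy sinusoids.  The FNN dimension selector uses the classic
Rtol = 10 / Atol = 2 criteria with a rounding-noise floor: coordinate
jumps below 1e−9 of the signal SD never mark a neighbor false (exactly
periodic signals give coincident embedded points whose 0/0 distance
ratio is otherwise meaningless).  The pipeline fixes (m = 3, τ = 4)
globally rather than per cycle.

The recurrence threshold ε is the 10%-quantile of pairwise trajectory
distances, i.e. a fixed recurrence rate per image — the standard
convention that makes RPs comparable across cycles; a global-ε option
exists (`EmbeddingParams.epsilon`).  The Heaviside convention is
Θ(0) = 1, fixed so tests can be bit-exact.

GASF is computed in trigonometric form; the algebraic identity
`cos(φ_i+φ_j) = x̄_i x̄_j − √(1−x̄_i²)√(1−x̄_j²)` agrees to 1e−12 and
serves as the test oracle.  Inputs outside [0,1] by more than 1e−9 are
rejected; smaller excursions are clamped.

MTF quantile edges come from the cycle itself (per-image); ties on an
edge go to the lower bin; unoccupied transition rows stay zero (never
indexed by construction); a constant cycle yields the all-ones field
and a degenerate flag.

RP matrices have side `224 − (m−1)τ = 216`; they are enlarged to
224×224 by nearest-neighbor lookup, which preserves the binary texture
(bilinear smoothing would invent gray levels).  GASF maps [−1,1] to
[0,1] via `(g+1)/2`; images stay float planes in [0,1] replicated to 3
channels; PNG export quantizes to 8 bits for visualization only.

## Classifiers and complexity accounting

Parameter and FLOP accounting for MobileNetV3-Small and ResNet-18 is an
analytic audit over declarative layer tables: every conv (with groups),
batch-norm (2 trainable scalars per channel) and linear layer is
enumerated with exact shapes.  With 2-way heads the audit gives
1,519,906 and 11,177,538 parameters.  FLOPs are defined as 2× the
multiply–accumulates of conv and linear layers at 3×224×224 — the
convention is printed in every report because published FLOP figures
are convention-dependent; under it ResNet-18 lands at 3.627 G and
MobileNetV3-Small at 0.111 G.  Model size is 4 bytes per parameter.

The trainable classifiers are compact numpy networks with hand-written
backprop (verified against finite differences in the test suite):

* `compact_cnn` for 224² images: 4× average pool → conv 3→16 (3×3,
  stride 2) → ReLU → conv 16→32 (3×3, stride 2) → ReLU → global average
  pool → linear 32→2.  Deliberately narrow so a full train/validate
  cycle runs in minutes on one CPU core; phase-space textures at this
  class contrast are low-frequency enough for two conv stages.
* `cnn1d` for raw 224-sample cycles: four strided conv blocks
  (16/32/64/128 channels) → global average pool → linear head, matching
  its audited layer table parameter-for-parameter.

Training follows a fixed protocol: AdamW (lr 1e−3, weight decay 1e−4,
decoupled), step decay ×0.5 every 10 epochs, batch size 32,
cross-entropy, up to 40 epochs, seed 42, and best-model saving by
validation AUC.  Everything is plain single-threaded numpy, so two runs
with the same seed are bit-identical — the determinism tests assert
equality, not tolerance.  Networks train from scratch; no pretrained
weights are involved anywhere.  One consequence of short schedules is
calibration: after a few epochs the softmax probabilities cluster near
0.5, so ranking metrics (AUC) saturate long before threshold metrics at
0.5 look sensible.  The decision threshold defaults to 0.5 and is
configurable.

Grad-CAM targets the feature map after the last conv stage's ReLU:
channel weights are spatially averaged gradients of the target-class
logit, the weighted sum is rectified, upsampled by nearest neighbor to
224² and min–max normalized; an everywhere-zero gradient yields a zero
map with a warning.

## Fusion and metrics

`P_final = w·P_RP + (1−w)·P_GASF` with one global weight chosen by
exhaustive grid search (step 0.05, 21 candidates) maximizing validation
AUC; ties resolve to the smallest w, making the search deterministic.
Because both endpoints are candidates, the fused validation AUC can
never be below either single modality.  Fusion operates on per-cycle
probabilities; the weight is frozen for inference.

AUC is the rank-based Mann–Whitney estimator with average ranks (ties
count 1/2).  The AUC interval is Hanley–McNeil:
`SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)]/(n₊n₋)`,
`Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`, with the Q₁ term attached to the
positive-class count.  Proportions get Wald intervals with z = 1.96
exactly; all intervals clip to [0,1].  Metrics are computed at cycle
level, but `metrics_report(ci_n=…)` lets the caller supply
subject-level counts to the CI formulas when the evaluation unit and
the independence unit differ.

## Problem sizes

The default end-to-end experiment uses 40 subjects (20 per class), 20
cycles each, RP + GASF classifiers trained 5 epochs — about 750 cycles
and half a minute on one CPU core.  The fusion weight-recovery
experiment uses 20,000 calibrated scores (independent Gaussian noises
with variance ratio 2:3 around a shared signal, whose precision-
weighted optimum is w = 0.6).  Encoder and embedding oracles run on
trajectories up to 60 points and series up to 20,000 samples.

## Known limitations

* The synthetic contrast is generous; sensitivity of the pipeline to
  class overlap, label noise or rhythm pathology is untested.
* The MobileNetV3/ResNet audits count; they do not run.  Latency and
  on-device figures are out of scope.
* Beat detection assumes a dominant QRS-analog deflection; heavily
  non-sinus morphologies would need retuned band and threshold
  constants.
* MI-based delay selection is estimator-dependent near determinism (see
  above); the pipeline therefore fixes (m, τ) globally instead of
  trusting per-cycle estimates.
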