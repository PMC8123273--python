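# Methods

This document records the models, parameter values, and numerical
conventions used throughout the package, and the limitations that come
with working on synthetic data.

## RR-interval generator

Each session is a sequence of RR intervals (ms)

```
RR_i = AVNN + A_lf · sin(2π f_lf t_i) + A_hf · sin(2π f_hf t_i) + ε_i
```

with `f_lf = 0.10 Hz`, `f_hf = 0.25 Hz`, `ε_i ~ N(0, σ²)` i.i.d., `t_i`
the cumulative beat time, and a hard floor of 300 ms. Beats are drawn
until the cumulative time covers the requested duration.

State defaults (state 0 = morning/alert, 1 = afternoon, 2 =
evening/fatigued):

| state | AVNN (ms) | A_lf (ms) | A_hf (ms) | σ (ms) |
|-------|-----------|-----------|-----------|--------|
| 0     | 698.18    | 39.6      | 20.1      | 14.9   |
| 1     | 740.27    | 35.0      | 20.5      | 16.1   |
| 2     | 817.93    | 31.0      | 10.3      | 23.9   |

The amplitudes and jitter per state were calibrated jointly against
three closed-form constraints so the generated windows reproduce
plausible per-state index means:

- `RMSSD² = 2A_lf² sin²(π f_lf T) + 2A_hf² sin²(π f_hf T) + 2σ²` with
  `T = AVNN` (the mean beat period);
- the LF/HF split of each component: the sinusoids contribute to their
  own bands, the white jitter spreads uniformly up to the beat Nyquist
  `1/(2T)`, giving a predicted LFnorm;
- the lag-1 autocorrelation ρ of the successive differences, which
  fixes the ternary monotone-quadrant share through the orthant formula
  `P(A++) = 1/4 + arcsin(ρ)/(2π)` (white jitter contributes −0.5 to ρ).

The resulting trends — AVNN and RMSSD rising, LFnorm and the monotone
quadrant shares falling with fatigue — are the intended physiological
signature (vagal tone increasing with fatigue).

Cohort structure: every participant receives one session per state. A
participant-level offset `~N(0, 30 ms)` shifts AVNN identically in that
participant's three sessions, emulating stable inter-individual
resting-heart-rate differences; 30 ms keeps the between-participant
spread smaller than the ~40–80 ms between-state separation, so states
remain learnable from held-out participants while the participant split
still matters. Session seeds derive deterministically from
`(master seed, participant, period)` so any session can be regenerated
in isolation.

## ECG synthesis and noise

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with fixed
amplitudes (0.15, −0.10, 1.00, −0.15, 0.30 mV), offsets (−200, −22, 0,
22, 250 ms relative to the R peak) and widths (25, 10, 12, 10, 45 ms),
sampled at 512 Hz. Noise components — white (`σ` in mV), 50 Hz mains,
0.25 Hz baseline wander, and band-limited muscle artifact — are
additive; all random draws are made unconditionally from the noise
seed so that enabling one component never changes another's
realization.

## Denoising

1. Zero-phase filter chain: 50 Hz IIR notch (2 Hz bandwidth), 4th-order
   Butterworth low-pass at 100 Hz, 4th-order Butterworth high-pass at
   0.5 Hz, all applied forward-backward.
2. Wavelet shrinkage: db4 decomposition at level 4; for each detail
   level the noise scale is `σ̂ = MAD/0.6745` and the threshold is the
   universal rule `σ̂ √(2 ln N)`, applied softly. A literal variant
   `T = 2 ln N` (no noise scale) is available behind the
   `threshold_rule="printed"` switch for comparison; it is not the
   default because it ignores the noise level entirely.

## R-peak detection

Per 10-s segment the amplitude threshold is
`(max − min) · 0.7 + min`. Local maxima (strict first-difference sign
change) above the threshold are peak candidates; candidates closer than
200 ms are merged, keeping the larger amplitude. The rule is invariant
to amplitude scaling by construction. Detected peak times convert to RR
intervals in ms; intervals outside [300, 2000] ms are flagged as
artifacts.

## Windowing

RR series are cut into 100-s half-open windows by the time of the
interval's end beat. A window is *effective* when it holds at least 40
intervals and at most 20% artifact flags; only effective windows enter
the feature table. A 1800-s session yields 18 windows.

## HRV indexes

21 indexes per window. Time domain: AVNN, AVHR = 60000/AVNN, SDNN
(ddof = 1), CV = 100·SDNN/AVNN, RMSSD, SDSD, pNN50, pNN20. Frequency
domain: the RR series is resampled to 4 Hz by cubic interpolation and
Welch's method (50-s segments, 50% overlap, linear detrend) estimates
the spectrum; band powers are trapezoid integrals over LF
(0.04–0.15 Hz), HF (0.15–0.40 Hz) and total (0.003–0.40 Hz); derived
ratios are LF%, HF%, LFnorm = LF/(LF+HF), HFnorm, LF/HF. A
Lomb–Scargle estimator on the unevenly sampled series is available as
an alternative (`spectral_method="lomb"`); the two agree on normalized
band powers. Nonlinear: Poincaré SD1/SD2 from the rotated lag-1
scatter (SD1 along the line of identity's normal), ellipse area
S = π·SD1·SD2, and the ternary difference scatter shares A++ (both
successive differences positive) and B−− (both negative), as
percentages of the n−2 difference pairs.

Constant windows make the spectral ratios undefined; they are flagged
and excluded rather than coerced.

## Feature screen (Friedman test)

For each index, blocks are (participant, window index) pairs observed
in all three states; incomplete blocks are an error, not silently
dropped. The statistic uses within-block ranks:

```
X² = 12 / (n m (m+1)) · Σ_j R_j² − 3 n (m+1)
```

with the standard tie correction by default, referred to a χ² with
m−1 degrees of freedom. For very small designs an exact permutation
p-value enumerating all `(m!)^n` within-block orderings is available
and is used as the test oracle. Indexes with p < α (default 0.05)
survive; constant columns are excluded with a warning.

## Principal component analysis

PCA is computed on the correlation matrix (eigendecomposition via
`eigh`), i.e. each index is standardized before extraction, so scale
differences between ms-valued and dimensionless indexes do not drive
the components. Loadings are `√λ · u`; each eigenvector's sign is fixed
so its largest-magnitude element is positive. The retained count is the
smallest k whose cumulative contribution rate `Σλ_i / p` reaches 85%.
With the three-latent-source RR model above, three components typically
clear the threshold.

## LVQ classifier

LVQ1 with 13 prototypes allocated over the 3 classes by largest
remainder (5/4/4). Prototypes initialize from random training samples
of their class. Training runs up to 1000 epochs over a per-epoch
shuffle; the learning rate decays linearly from 0.01 to 0 across the
epoch budget. The winning prototype (squared Euclidean distance,
ties to the lowest index) moves toward same-class samples and away
from others by `lr · (x − w)`. After each epoch the one-hot mean
squared error on the training set is recorded; training stops early
when it reaches 0.1 (for 3 classes this equals an error rate of 0.15).
Competitive-layer size can be selected by stratified k-fold
cross-validated accuracy over a candidate list.

Baselines share the train/test split and evaluation code: a
back-propagation neural network (one hidden layer of 13 units) and an
RBF support-vector machine.

## Evaluation

The report contains the confusion matrix, overall accuracy, per-class
(row-normalized) accuracy, per-class and macro precision and recall,
and two F1 conventions: the standard `2PR/(P+R)` and an
accuracy-substituted variant `2PA/(P+A)` that uses overall accuracy A
in place of recall. Both are reported so either convention can be
compared against external figures. One-vs-rest ROC curves and AUCs use
negative class distances as scores.

Train/test splits hold out whole participants (default 8 of 30), so
the test metrics measure generalization to unseen individuals, not
unseen windows of seen individuals.

## Numerical conventions

- All computation in float64; standard deviations use ddof = 1 unless a
  population convention is stated (Poincaré exposes `ddof`).
- Every stochastic step takes an explicit seed; cohort session seeds
  spawn from `numpy.random.SeedSequence` tuples, so runs are exactly
  reproducible and sub-seeds are independent.
- Band powers use trapezoidal integration on the estimated spectrum.
- The pipeline writes a config hash (SHA-256 of the canonical JSON
  config) into every run report so artifacts are traceable to their
  settings.

## Limitations of synthetic data

- The RR model is two sinusoids plus white noise: its spectrum has
  line components rather than the broadband 1/f-like structure of real
  HRV, and its nonlinear indexes inherit Gaussian-linear geometry.
  Absolute band powers are therefore not comparable to field
  recordings; ratios and trends are.
- Fatigue states are encoded by construction, so classification
  accuracy here is an upper bound on what identical methods achieve on
  real recordings, and is useful mainly for verifying the pipeline
  end-to-end and comparing classifiers under identical conditions.
- The ECG template has fixed morphology; detector robustness to
  morphology variation (ectopy, bundle-branch shapes) is untested by
  design.
- Artifact flags only catch out-of-range intervals; real preprocessing
  needs ectopic-beat and missed-beat correction.
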