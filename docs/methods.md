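# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `ecgsurv`. Everything stated here
is computed by the package's tests or by `scripts/acceptance.py`; no
external results are quoted.

## Problem setting

The package addresses discrete-time survival prediction from raw 12-lead
electrocardiograms under right censoring. Each record is a 10 s, 500 Hz
trace stored as a 12 x 5000 matrix in millivolts. Follow-up is one year,
discretised into 12 monthly bins: bin *k* covers the half-open interval
(*k*, *k*+1] months. A subject alive at 12 months is administratively
censored at the horizon (bin 11). Subjects may also be censored earlier by
an independent uniform mechanism.

## The waveform survival model

A 1-D residual convolutional encoder maps the (optionally decimated)
waveform to a feature vector:

- stem convolution (kernel 15, stride 2), then one channel-preserving
  residual block and three channel-doubling, stride-2 residual blocks;
- every convolution is followed by batch normalisation, ReLU, and dropout
  (rate 0.2), matching the conv-BN-ReLU-dropout ordering throughout;
- hybrid pooling concatenates the global maximum and global mean of each
  channel over time;
- a single fully connected softmax layer with 12 neurons emits the
  probability mass function (PMF) p over the monthly bins. The cumulative
  incidence function (CIF) is F_k = sum_{j<=k} p_j and predicted survival
  is S_k = 1 - F_k.

Kernel sizes, widths and block multiplicity are configuration
(`EncoderConfig`), because they are generic architecture hyperparameters
rather than part of the model definition. A ResNet-18-depth variant is one
config change (`blocks_per_stage=2`).

### Loss

Training minimises the DeepHit-style single-event objective

    L = mean_i NLL_i + alpha * mean_{(i,j) acceptable} eta(F_i(k_i), F_j(k_i))

- Event in bin k: `NLL = -log(p_k + eps)`.
- Censored in bin c: `NLL = -log(sum_{k>=c} p_k + eps)`. The censoring bin
  itself is included in the survivor mass: a subject censored within bin c
  may still fail inside it, and — decisively — the administratively
  censored majority censors in bin 11, where excluding the bin would leave
  zero mass under a 12-way softmax head.
- Ranking: a pair (i, j) is acceptable when i has an event in bin k_i and
  j's observed bin is strictly later; `eta(a, b) = exp(-(a - b) / sigma)`
  is the convex DeepHit kernel. The pair term is **averaged**, not summed,
  so the ranking weight is batch-size invariant.

Defaults `alpha = 0.1`, `sigma = 0.1` follow the DeepHit reference
ballpark; both are exposed in `LossConfig`. `eps = 1e-8` guards the
logarithms. Day-granularity labels convert at 30.44 days/month. Only the
single-event formulation is implemented; competing risks are out of scope.

The loss is implemented twice on purpose: a closed-form NumPy version
(`discrete_survival.total_loss`) that the tests pin to hand-derived values
(ln 12 for an event under a uniform PMF; -ln 0.75 for censoring in bin 3;
exp(-8) for the specified ranking pair), and a differentiable version
(`total_loss_from_logits`) used for training. A unit test asserts their
exact equivalence, and the analytic gradient is checked against central
differences to 1e-4 relative error.

### Training

Adam, full-scale defaults learning rate 1e-4, batch 512, 5 epochs
(`TrainConfig`). The desk-scale reference run in `benchmarks.py` uses
decimated 12 x 1000 inputs (factor-5 window averaging), 16 base channels,
batch 64, learning rate 1e-3 with cosine decay, 16 epochs: with only ~1000
optimiser steps, the full-scale learning rate would not converge, and the
decay removes the Adam noise ball that otherwise leaves the PMF head
miscalibrated. Decoupled (AdamW-style) weight decay is available in
`TrainConfig` but off by default — at desk scale it measurably changed
neither discrimination nor calibration. Training refuses event-free
cohorts (degenerate likelihood) and is bit-reproducible for a fixed seed
on a fixed BLAS configuration.

The softmax head's bias is initialised to the logarithm of the cohort's
discrete product-limit marginal PMF (life-table hazards over the training
labels, surviving mass absorbed into the final bin). Rationale: the
censored likelihood term constrains only sums of tail mass, so the
allocation of that mass across bins is likelihood-flat; prior-initialising
the head starts those flat directions at the calibrated marginal instead
of the uniform PMF, roughly halving the early-training calibration gap at
unchanged discrimination. A `head_bias_init="zero"` switch restores plain
initialisation.

### Calibration behaviour at desk scale

Two effects bound how closely the mean predicted survival curve can track
the Kaplan-Meier estimate in the reference runs. First, a 12-way softmax
over bins that partition the year cannot represent survival past the
horizon: predicted S at the month-12 edge is identically 0 while the KM
estimate there is ~0.36 under the default conditions, so the 12-edge mean
absolute gap has a floor of about 0.03 from that edge alone (the final
bin's mass conflates month-12 deaths with survivors by design of the
censoring convention). Second, mid-training the event-likelihood gradients
outweigh the censored survivor-mass gradients, and mean cumulative
incidence drifts a few points above the observed curve on training and
test data alike; the imbalance fades only with many more optimiser steps
than desk-scale budgets provide. The measured gap in the reference run is
therefore ~0.06-0.09 across seeds rather than the ~0.01-0.02 KM sampling
noise a fully converged, fully expressive model would show. The drift is
not caused by the ranking term (removing it makes calibration
substantially worse) and is not overfitting (train-set and test-set gaps
match). At the same plateau the test C-index sits ~0.05-0.08 below the
true-latent-risk oracle, with a few points of seed-to-seed spread from the
cohort draw and training stochasticity.

## Neural-network substrate

Both networks run on a small reverse-mode automatic-differentiation engine
over NumPy (`ecgsurv.nn`): conv1d (stride/dilation/asymmetric padding via
im2col and BLAS matmul), batch norm, dropout, pooling reductions, and Adam.
The engine's operator gradients are tested against central differences and
the convolution against `scipy.signal.correlate`. Float32 is used
throughout the networks; the engine coerces Python scalars to the graph
dtype so no silent float64 promotion occurs.

## Risk scalar and the sequence model

The 12-point PMF is reduced to a scalar by the composite trapezoidal rule
with unit spacing, `sum_k (p_k + p_{k+1})/2 = 1 - (p_0 + p_11)/2`: 11/12
for a uniform PMF, 1 for interior one-hots, 1/2 for boundary one-hots, and
linear in the PMF. An alternative per-exam scalar — the predicted one-year
survival S_11 — is selectable in configuration; with a softmax head it is
zero up to normalisation error, so the trapezoid AUC is the default.

Serial examinations become the interleaved vector
(e_1, i_1, e_2, i_2, ..., e_n) of risk estimates and whole-week intervals
(`floor(days/7)`, zero allowed for same-week exams), zero-padded at the
tail to length 23 (up to 12 estimates, 11 intervals). Patients with a
single examination are excluded. When more than 12 examinations exist the
**most recent 12** are kept — a clinical-recency choice; the length rule
alone does not dictate which end to drop.

The sequence classifier is a temporal convolutional network: four residual
blocks, each two dilated causal convolutions (kernel 3, dilation 2^(L-1)
for block L, left-only padding), ReLU and dropout 0.1, then one fully
connected sigmoid readout of the final position's features. The receptive
field, 1 + 2(k-1)(1+2+4+8) = 61, covers the whole sequence and is asserted
at construction. Binary cross-entropy, Adam, full-scale defaults lr 5e-4,
batch 512, 10 epochs; the desk-scale benchmark uses 32 channels, lr 2e-3,
batch 64, 30 epochs for the same small-step reason as above.

## Censored-data evaluation

- **Time-dependent C-index**: pair (i, j) comparable when i events in bin
  k_i and j is observed strictly later (or censored in the same bin);
  concordant when F_i(k_i) > F_j(k_i); prediction ties earn 1/2; pairs of
  events in the same bin are not comparable. These are the standard
  Harrell/Antolini conventions; the estimator is pinned exactly against an
  O(n^2) brute-force enumerator on random censored datasets with ties, and
  is invariant under monotone transforms of all CIFs.
- **Bootstrap**: percentile intervals over subject-level resamples (whole
  patients, not records, when patient ids repeat); default 200 resamples.
- **Kaplan-Meier**: the product-limit estimator is implemented directly so
  the curve carries its at-risk/event tables; it is cross-checked against
  `lifelines.KaplanMeierFitter` to 1e-12.
- **Log-rank** wraps `lifelines.statistics.logrank_test` (chi-square, 1 df);
  **AUROC** wraps `sklearn.metrics.roc_auc_score` (tie-corrected). AUROC
  and the C-index coincide for a binary uncensored outcome, which is
  tested.
- **Calibration gap**: mean absolute difference over the 12 monthly edges
  between cohort-mean predicted survival and the KM estimate.

## The synthetic cohort generator

No public data accompany this problem, so the generator is a first-class
module and defines the study conditions.

**Waveforms.** Each beat is a sum of Gaussian deflections (P, Q, R, S, T)
at RR spacing 60/heart-rate seconds, plus a smooth ST-segment plateau
(sigmoid-edged, ~60-220 ms after the R peak) whose level is a free
parameter. Q and S amplitudes scale with the R amplitude (-0.12 and
-0.18). Each wave is projected to the 12 leads through a fixed weight
vector (lead II carries unit weight for every wave, so beat detection
thresholds lead II; precordial weights follow a loose R-progression), so
leads are correlated but distinct. White noise (SD ~0.02-0.04 mV) and
0.33 Hz sinusoidal baseline wander (~0.04-0.12 mV) are added. Gaussians
are evaluated on +-6-sigma windows; the truncated tails are below float32
resolution.

**Outcomes.** A subject's latent risk is z = sum_f beta_f (x_f - mu_f) /
sigma_f over the morphology features (P amplitude, R amplitude, T
amplitude, ST level), with defaults beta = (-1.2, -1.5, -0.6, -1.8): high
risk corresponds to a flatter P wave, lower R wave and depressed ST — the
direction the waveform-analysis literature associates with mortality risk.
The per-bin hazard is h_k = logistic(logit(h0) + z) with baseline h0 =
0.15 per bin (~80% one-year event probability at z = 0); the event bin is
drawn sequentially and the event time uniformly within its bin. Subjects
event-free at 12 months are administratively censored; uniform(0, 12]
censoring is applied with a probability tuned toward the target overall
censoring fraction (default 0.35, of which ~0.33 is administrative under
the default effect sizes). An unattainable target emits a warning and
proceeds with the closest achievable rate.

Under these defaults a 1000-subject cohort shows ~65% events and an oracle
(true-z) time-dependent C-index near 0.88, leaving visible headroom
between a learned model and chance.

**What the generator does not emulate**: real ECG morphology variation
(axis deviations, bundle-branch blocks, arrhythmias, pacing), device
filtering, inter-beat variability beyond seeded noise, informative
censoring, and competing risks. Passing recovery tests therefore shows the
pipeline can extract amplitude-coded hazard signal from clean multichannel
waveforms — not that it matches clinical performance on hospital data.

## Interpretation tools

Saliency is |d target / d input| in eval mode (deterministic inference
function). The differentiated scalar defaults to the trapezoid PMF-AUC
risk: the cumulative incidence at the horizon, the nominal "1-year risk",
is identically 1 under a softmax head whose bins partition the year, so
its gradient is zero and it cannot serve as a target. Any single bin's
probability is selectable instead (`target_bin`). For a linear model the
saliency equals |w| exactly, which is tested.

Median waveforms: R peaks are detected on 0.5-40 Hz band-passed lead II by
threshold peak-picking (half the trace maximum, 300 ms minimum spacing);
600 ms windows (200 ms before to 400 ms after the peak — a convention,
config-exposed) are cut and the per-lead, per-sample median over all beats
of all records is returned. The median is robust to occasional corrupted
beats, which is tested with a gross-outlier beat.

## Reference experiments (desk scale)

`benchmarks.py` defines the package's reference runs, which
`tests/test_acceptance.py` asserts on and `scripts/acceptance.py` reports:

- **Risk recovery**: 5000 simulated subjects (4000 train / 1000 test),
  default strong effects, ~35% censoring; encoder as above. Measured: test
  C-index vs the oracle C-index, the KM calibration gap, and the log-rank
  p-value between median-split predicted-risk groups.
- **Null control**: the identical pipeline with all effect sizes zero, run
  at 1200/600 and 2 epochs — under a null generator the chance-level
  conclusion does not depend on training scale, and the reduced size keeps
  the control cheap relative to the main run.
- **TCN separable rule**: 2000/1000 synthetic sequences labelled by
  "last estimate > 0.5"; test accuracy. **TCN null**: coin-flip labels;
  test AUROC.

## Known limitations

- The NumPy substrate trains at desk scale only; there is no GPU path, no
  mixed precision, and no grid-search harness beyond the config surface.
- Bit-level training reproducibility assumes a fixed single-threaded BLAS;
  across BLAS builds, results may differ in the last few bits.
- The Kaplan-Meier comparison uses record-level curves; the age/sex
  weighted variants used in some cohort analyses are not implemented.
- The saliency tool offers input gradients only (no Grad-CAM, SHAP or
  occlusion), and no clinical interpretation is attempted.
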