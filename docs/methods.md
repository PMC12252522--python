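# Methods

This note documents the models, procedures and numerical choices behind
`gaitphys`, and what its synthetic-cohort tests do and do not demonstrate
about real clinical gait data.

## Data model

The atomic unit is one gait cycle of one series — a joint angle, a
ground-reaction-force (GRF) component, or a joint moment/power — expressed
on a uniform 0–100% time base from heel strike to the next ipsilateral
heel strike, nominally ~200 samples. Cycles nest inside sides (left/right)
inside subjects; subjects carry a clinical group label, age (years) and
normalised walking speed (walking speed divided by limb length, 1/s).
The default series inventory is 24 curves: 5 joints (pelvis, hip, knee,
ankle, foot) × 3 planes (sagittal, coronal, transversal), 3 GRF
components, and moments + powers of hip, knee and ankle.

Resampling between resolutions is linear interpolation on the closed
[0, 100]% grid: shape-preserving, ringing-free, and endpoint-exact, so
resolution sweeps stay monotone-interpretable. Sub-windows are index
slices `floor(start·N/100) .. floor((start+length)·N/100)`, with the
stance/swing boundary at the conventional 60%.

## The four per-cycle metrics

All metrics are computed per (cycle, series) with natural logarithms.

* **Shannon entropy (SE)** of the value histogram, `B = round(√N)`
  equal-width bins spanning `[min, max]` of the individual series.
  Range `[0, ln B]`; 0 for a constant series.
* **Permutation entropy (PE)**: entropy of the ordinal-pattern
  distribution with embedding dimension `D = 4` and delay `τ = 1`
  (consecutive samples; the short per-cycle series argue for a small D).
  Ties rank by position — earlier sample lower — for determinism.
* **Weighted permutation entropy (WPE)**: each window's pattern weighted
  by its variance `w = (1/D) Σ (x_k − x̄)²`, weighted probabilities
  normalised to sum to one (the established normalised form). Undefined
  (reported missing) when every window has zero variance.
* **BDS statistic**: `W = √M (C_m(ε) − C_1(ε)^m)/σ_m(ε)` with the
  published asymptotic variance, `m = 2`, `ε = 0.5·sd` by default, both
  configurable, plus an optional increments mode. `C_1` is estimated on
  the full sample rather than the truncated one some implementations
  use; this makes `W` *exactly* invariant under time reversal (the set
  of embedding-vector distances is reversal-invariant) at an `O(1/N)`
  difference from the truncated convention, and the statistic remains
  asymptotically standard normal under independence (verified by
  simulation in the tests: mean within ±0.1, sd within [0.8, 1.25] at
  N = 500). Undefined below 20 samples and reported missing there.

Metrics undefined for a particular cycle are recorded as missing, never
dropped; classification imputes them with training-fold medians, and the
automatic feature selection drops a column only when it is missing for
every row (e.g. BDS at 11 samples/cycle).

## Classification protocol

Cycle-level feature rows (one per subject × side × cycle; columns =
series × metric) feed a random forest with 500 trees and otherwise
standard settings (Gini, unlimited depth, √d feature subsampling,
bootstrap). Scores are *subject-level*: per realisation the larger
group's subjects are subsampled to the smaller group's size, then each
subject in turn is held out, the forest is trained on the remaining
subjects' rows, and the held-out subject is assigned the majority vote
over its rows (ties resolved by mean predicted probability). Precision =
fraction of subjects correct; the reported score is the mean over
realisations (default 100). Both sides of a subject always travel
together, so train/test subject sets are disjoint by construction.

Two design points deserve emphasis:

* **Fold rebalancing.** Holding one subject out of balanced groups
  leaves its class under-represented (9 v 10), and majority voting
  amplifies that into a strongly pessimistic bias — simulation puts the
  "uninformed" baseline near 0.30 rather than 0.5. Each fold therefore
  also drops one randomly chosen subject of the opposite group, making
  every training fold balanced and restoring the 0.5 baseline that the
  score's interpretation ("0.5 = no information, 1.0 = perfect")
  presumes.
* **Null-baseline estimation.** Conditional on a single fixed cohort,
  leave-one-out outcomes are nearly deterministic, so the mean over
  protocol realisations concentrates on a cohort-specific value whose
  across-cohort sd is ~0.06 even for unclustered features. The
  uninformed-baseline experiment (`gaitphys.calibration`) therefore
  draws a fresh null cohort per realisation; by exchangeability its
  expectation is exactly 1/2, with Monte-Carlo error ~0.006 at 100
  realisations.

The forest itself is an in-package numba-compiled implementation of the
standard Breiman algorithm (identical ingredients to the scikit-learn
classifier's defaults), written because the protocol fits thousands of
500-tree forests and per-fit overhead dominates on one core. The
scikit-learn backend remains selectable (`TaskSpec(backend="sklearn")`),
and the test suite checks the two backends' accuracy, probabilities and
impurity importances against each other; a separate test reproduces the
whole protocol's scores exactly against an independent reimplementation
sharing only the seed derivation.

Feature importances are impurity-based, averaged over balanced
realisations and rescaled so the top feature is exactly 1.0. Transfer
("cross-dataset") scoring fits on one cohort's balanced subsample and
majority-votes every subject of the other cohort; imputation statistics
come from the training block only.

## Mixed-effects metric models

For one metric of one series, the cycle-level value is modelled as

    metric ~ age_c + speed_c + condition + condition:age_c + condition:speed_c
             + (1 | subject) + (1 | side within subject)

with the healthy/control group as the reference level and age/speed
centred at 10 years and 1.0 1/s. The default backend is REML via
statsmodels `MixedLM` with Wald 95% intervals — frequentist coverage
semantics, not posterior credibility; the scientific content is the
fixed-effect structure and the nesting, not the estimation engine.
Boundary fits (side variance ≈ 0) are legitimate and surfaced as
warnings; optimisation falls back across several optimizers before
declaring failure. For forest-plot-style reporting, coefficients and
intervals are divided by the pooled across-group standard deviation of
the response, `√(Σ_g (n_g−1)s_g² / Σ_g (n_g−1))`.

## Residual-network benchmark

The deep reference model is an 11-layer 1-D residual network — three
blocks of three convolutions (kernel sizes 8/5/3), so 9 convolutional
layers, then global average pooling over time and a softmax classifier;
identity shortcuts span each block, with 1×1 projections (conventionally
not counted towards depth) where channels change. It is implemented in
numpy with manual backpropagation and Adam, and its gradients are
verified against finite differences in the tests. Because leave-one-out
retraining of a deep model is not sensible, scoring uses subject-grouped
5-fold cross-validation with the same balancing and majority-vote
aggregation as the feature protocol. Desk-scale defaults (16/32/32
filters, input length 100, ≤30 epochs) make it a reference point, not a
production classifier.

## Synthetic cohort generator

Each series of each cycle is a band-limited harmonic template plus
dynamical and measurement noise:

    cycle = waveform(subject, side, series) + bump
          + gain(subject) · AR1_skew + cycle_noise_sd · N(0,1)

* The waveform is a sum of `n_harmonics = 6` sinusoids with shared
  per-series base amplitudes/phases, per-subject offsets (sd
  `subject_sd = 0.1`) and smaller per-side offsets (sd `side_sd = 0.05`;
  real gait is never perfectly symmetric, and the side-within-subject
  variance component of the mixed model needs a truth to estimate),
  evaluated on the warped grid `u = t^(1+asymmetry)` so rise and fall
  durations differ; normalised to zero mean, unit sd.
* Group-level effects are explicit parameters, never resampled
  randomness: per-harmonic template offsets, a Gaussian bump localised
  in cycle time (amplitude/centre/width, optionally restricted to named
  series), a per-series noise-gain override, and the warp asymmetry.
  Groups configured identically are exchangeable by construction.
* The dynamical noise is AR(1) (`α = 0.3`) with mean-centred exponential
  innovations — memory plus non-Gaussianity, the two classical sources
  of time irreversibility; Gaussian innovations and `α = 0` recover
  white noise. Its amplitude `noise_gain = 0.15` is the entropy control.
* Covariate effects enter log-linearly:
  `log gain_i = log noise_gain + age_coef (age_i − 10) + speed_coef (speed_i − 1)`,
  with ages uniform on [4, 16] years and speeds normal around 1.0 1/s
  (sd 0.2, floored at 0.3). This is the documented ground truth that the
  mixed-model recovery tests target. Injected magnitudes in the tests
  (`age_coef = 0.12`/yr, `speed_coef = −2.0` per 1/s) were chosen by a
  design-stage power calculation to give recovery z-scores ≈ 5 at 10
  subjects/group.
* Cycle counts per side are uniform on 2–5; 200 samples/cycle; the
  series inventory defaults to the full 24 curves and is configurable.

Known behaviour worth noting: permutation entropy increases monotonically
with `noise_gain` throughout the working range, but Shannon entropy
saturates near gain ≈ 0.15 and then declines (the value distribution
turns unimodal, and equal-width-bin entropy drops), so joint SE/PE
monotonicity is only asserted below that point. With random phases the
waveform *ensemble* is statistically time-symmetric regardless of warp;
the warp's irreversibility effect is per-realisation and is tested as a
paired comparison.

What the generator does **not** emulate: biomechanically consistent
inter-joint coupling, force-plate physics, marker dropout, manual cycle
QC, or the heavy-tailed subject heterogeneity of real cerebral-palsy
cohorts. Passing tests therefore demonstrate that the pipeline recovers
effects it is pointed at under controlled conditions — not that the
clinical effect sizes of real cohorts are reproduced.

## Problem sizes used in the tests

The test suite favours many small experiments over few large ones:
signal-recovery and transfer experiments use 6–8 subjects/group with a
3–15 series inventory; the resolution sweep uses lengths {11, 30, 200}
at 50 realisations; mixed-model calibration uses 50 replicate cohorts of
10 subjects/group and one series; the uninformed-baseline experiment is
the full-size one (10 subjects/group, all 24 series, 100 cohort
realisations, 500 trees).

## Limitations

* The BDS statistic is formally reversal-invariant; group differences in
  it reflect dynamical structure (memory, nonlinearity) rather than a
  signed arrow of time, and the default raw-series mode on smooth
  waveforms yields large positive values driven by autocorrelation.
* Wald intervals from REML on ~20 subjects are mildly anti-conservative
  (measured null coverage 0.93–0.98 per term).
* The numpy residual network trains on one core at desk scale only; no
  augmentation, scheduling, or architecture search.
* Long-format CSV I/O is the only on-disk format; motion-capture (C3D)
  ingestion is out of scope.
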