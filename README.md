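# gaitphys

Statistical-physics features of clinical gait time series: per-cycle
entropy and time-irreversibility metrics, a subject-level classification
protocol for comparing clinical groups, mixed-effects models of
metric–covariate relationships, a deep-learning reference benchmark, and
a synthetic gait-cohort generator that makes the entire pipeline testable
without access to clinical recordings.

## Who this is for

Movement-analysis and biomedical-signal researchers who represent gait as
per-cycle curves — joint kinematics (5 joints × 3 planes), ground
reaction forces, joint moments and powers, each on a 0–100% cycle time
base — and want interpretable dynamical descriptors of those curves and
a sound protocol for asking whether the descriptors separate clinical
groups (e.g. typically developing children vs. idiopathic toe walking,
cerebral palsy, or hereditary spastic paraplegia).

## The metrics

For each cycle of each series, four scalars (natural log throughout):

* **Shannon entropy** `E = −Σᵢ p(i) ln p(i)` over `round(√N)` equal-width
  amplitude bins — uncertainty of the value distribution.
* **Permutation entropy** `PE = −Σᵢ p(πᵢ) ln p(πᵢ)` over ordinal patterns
  of embedding dimension `D = 4` — uncertainty of the local ordering
  structure.
* **Weighted permutation entropy** — the same with each window weighted
  by its variance `wᵢ = (1/D) Σ_k (x_k − x̄)²`, damping low-amplitude,
  noise-dominated patterns.
* **BDS statistic** `W = √M (C_m(ε) − C₁(ε)^m)/σ_m(ε)` — a z-statistic
  against serial independence built from correlation integrals;
  asymptotically N(0, 1) under i.i.d., far from 0 for dynamics with
  memory or nonlinearity.

## The classification protocol

Cycle-level feature rows (columns = series × metric) feed a 500-tree
random forest. Scores are subject-level, balanced leave-one-out: per
realisation the larger group is subsampled to the smaller group's size;
each subject is held out in turn (both sides together), the forest trains
on the other subjects' rows (rebalanced after holdout), and the held-out
subject's class is the majority vote over its rows. Precision is the
fraction of subjects correct, averaged over 100 realisations: 0.5 means
the features carry no group information, 1.0 perfect separation. On top
of this sit impurity-based feature-importance rankings (top feature
rescaled to exactly 1.0), cross-cohort transfer scoring, and resolution
(samples-per-cycle) and sub-window (start%, length%) sensitivity sweeps.

## Worked example

Generate a synthetic cohort in which the "itw" group has elevated
dynamical noise in the ankle series only, extract features, score the
group pair and inspect what the model used:

```python
from gaitphys import (GroupParams, SyntheticConfig, TaskSpec,
                      generate_cohort, compute_features, features_to_wide,
                      loo_classification_score, feature_importance)

cfg = SyntheticConfig(
    groups=(GroupParams(name="control", noise_gain=0.15),
            GroupParams(name="itw", noise_gain=0.15,
                        series_noise_gain={"ankle_sagittal": 0.45,
                                           "ankle_coronal": 0.45,
                                           "ankle_transversal": 0.45})),
    n_subjects_per_group=8,
    seed=7,
)
cohort = generate_cohort(cfg)
features = compute_features(cohort)
wide = features_to_wide(features)

task = TaskSpec("control", "itw", n_realisations=20, n_trees=500, seed=0)
score = loo_classification_score(wide, task)
print(f"control vs itw: precision {score.mean_precision:.3f} "
      f"+/- {score.sd_precision:.3f}")
print(feature_importance(wide, task).head(5).round(3).to_string(index=False))
```

Output:

```
control vs itw: precision 1.000 +/- 0.000
                 feature  raw_importance  relative_importance
      ankle_coronal__WPE           0.113                1.000
       ankle_coronal__PE           0.095                0.843
  ankle_transversal__BDS           0.068                0.604
     ankle_sagittal__WPE           0.060                0.530
grf_anteroposterior__BDS           0.056                0.492
```

The injected ankle effect separates the groups perfectly, and the
importance ranking points straight back at ankle entropy features — the
weighted permutation entropy of the ankle in the coronal plane leads with
relative importance exactly 1.0.

The same pipeline is available from the shell:

```bash
gaitphys simulate --config cohort.yaml --out cohort.csv
gaitphys extract  --cohort cohort.csv --out features.csv
gaitphys classify --features features.csv --groups control,itw --seed 0
gaitphys resolution --cohort cohort.csv --groups control,itw
gaitphys subwindow  --cohort cohort.csv --groups control,itw
gaitphys effects    --cohort cohort.csv --metric PE --series ankle_sagittal --reference control
```

## Documentation

`docs/methods.md` describes the metric definitions and conventions, the
protocol design choices (fold rebalancing, null-baseline estimation),
the mixed-model structure, the residual-network benchmark, the synthetic
generator's ground-truth model, and known limitations.
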