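# szeeg

Multi-band resting-state EEG analysis for two-group (patient vs control)
cohorts: per-window feature extraction — relative band power, fuzzy entropy
and phase-lag-index functional connectivity — followed by ensemble
classification under 10-fold cross-validation, importance-based recursive
feature selection, and spatio-spectral group-difference reporting.  A
synthetic cohort generator with controllable, known group effects makes the
whole pipeline testable end to end without any clinical recordings.

The package targets the common pediatric-schizophrenia study design:
16-channel 10–20 montage (F3, F4, F7, F8, C3, C4, Cz, T3, T4, T5, T6, P3,
P4, Pz, O1, O2), 128 Hz sampling, ~60 s of eyes-closed rest per subject,
signals decomposed into Delta (0.5–4 Hz), Theta (4–8), Alpha (8–13),
Beta (13–30) and Gamma (30–45 Hz) and cut into non-overlapping windows.

## The three feature families

For each window (default 4 s = 512 samples):

- **Relative power (RP).** With the one-sided periodogram `P_x(f)` of the
  broadband (0.5–45 Hz) window,

      RP(band) = (Σ_{f ∈ [f_l, f_h)} P_x(f) / Σ_{f ∈ [f_n, f_m)} P_x(f))
                 × (f_m − f_n) / (f_h − f_l)

  i.e. the band's share of total power, bandwidth-corrected so a flat
  spectrum scores 1 in every band.  16 channels × 5 bands = 80 features.

- **Fuzzy entropy (FuzEn).** For a band-filtered window, mean-centered
  subsequences of length m and m+1 are compared under the fuzzy membership
  `exp(−ln2 · (d/r)²)` of their Chebyshev distance `d`;
  `FuzEn = ln O_m − ln O_{m+1}` where `O_m` averages memberships over all
  pairs.  Defaults m = 2, r = 0.2 × (window standard deviation), which
  makes the value scale-invariant.  Lower FuzEn = more regular signal.
  80 features.

- **Phase lag index (PLI).** For two band-filtered windows with
  instantaneous phases `φ_k`, `φ_l` from the Hilbert analytic signal,
  `PLI = |mean_t sign(φ_k(t) − φ_l(t))|` (phase differences wrapped to
  (−π, π], 5% of samples trimmed at each window edge).  PLI is 0 for
  identical or purely zero-lag coupled signals and 1 for a constant nonzero
  lag, making it insensitive to volume-conduction-like coupling.
  (16·15/2) pairs × 5 bands = 600 features.

Total: the canonical **760-column** feature table, one row per
(subject, window).

Classification uses four interchangeable ensemble learners (`rf`,
`xgboost`, `catboost`, `lightgbm` — each resolves to the corresponding
library when installed, otherwise to a scikit-learn stand-in; see
`docs/methods.md`), stratified 10-fold cross-validation, and
accuracy/precision/recall/F1 on the percent scale.  Feature selection ranks
all features by model importance and scans nested ranking prefixes for the
accuracy-optimal subset.

## Worked example

```python
from szeeg import (CohortConfig, ModelConfig, simulate_cohort,
                   extract_features, make_folds, cross_validate,
                   select_features, export_subset)

# 8 + 8 subjects, 20 s each, with the default planted group effects
config = CohortConfig(n_hc=8, n_scz=8, duration_s=20.0, seed=7)
recordings, manifest = simulate_cohort(config)

table = extract_features(recordings, window_length_s=4.0)
print(table.shape)                      # (80, 763) = 16 subj x 5 windows

mc = ModelConfig(model="catboost", seed=7)
folds = make_folds(table, n_folds=10, seed=7)
cv = cross_validate(table, mc, folds)
print(f"accuracy {cv.mean('accuracy'):.2f} +/- {cv.sd('accuracy'):.2f} %")

trace = select_features(table, mc, folds, stride=152)
print(trace.optimal_size, f"{trace.optimal_accuracy:.2f} %")
print(export_subset(trace))
```

Output:

```
(80, 763)
accuracy 98.75 +/- 3.95 %
1 98.75 %
        Delta  Theta  Alpha  Beta  Gamma  Total
family
RP          1      0      0     0      0      1
FuzEn       0      0      0     0      0      0
PLI         0      0      0     0      0      0
Total       1      0      0     0      0      1
```

The 80 windows separate almost perfectly because the planted effects are
large (30% band-power shifts, half the band variance replaced by a
deterministic oscillation, 10 coupled channel pairs at strength 0.6): the
selection curve already saturates at a single delta relative-power feature,
and ties break toward the smaller subset.  With `EffectSpec.neutral()` the
same pipeline classifies at chance.

The same workflow is scriptable from a shell:

```
szeeg simulate --n-hc 8 --n-scz 8 --duration 20 --seed 7 --out cohort/
szeeg extract  --in cohort/ --manifest cohort/manifest.csv --window 4 --out features.csv
szeeg train    --features features.csv --model catboost --folds 10 --seed 7 --out cv.json
szeeg select   --features features.csv --base-model catboost --stride 152 --seed 7 --out rfe.json
szeeg report   --features features.csv --rfe rfe.json --out report/
szeeg sweep    --in cohort/ --manifest cohort/manifest.csv --windows 1,2,4 --out sweep.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's analytic reference values
at run time — the phase-lag-index of a constant-lag sinusoid pair and of an
identical signal pair, both generated fresh from the given seed — and
writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
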