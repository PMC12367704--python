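# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generator does and does not emulate, and
the known limitations.  Nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

All filters are 4th-order Butterworth bandpasses applied forward-backward
(`scipy.signal.sosfiltfilt`), giving an effective 8th-order magnitude
response with zero net phase.  Zero phase matters: the phase lag index is a
pure phase statistic, and a causal filter would shift phases differently
across the band.

The processing order is fixed: broadband 0.5–45 Hz filter → average
reference (subtract the across-channel mean at every sample) → per-band
decomposition with the same filter family → segmentation into
non-overlapping windows, contiguous from sample 0, trailing remainder
dropped.  Decomposition precedes windowing so that windows carry no
per-window filter transients; the window segmentation is a pure reshape.

Numerical notes, measured with the shipped filters at 128 Hz:

- broadband stopband: |H(60 Hz)|² ≈ 2·10⁻⁶, but forward-backward edge
  transients of the 0.5-Hz corner decay over seconds — tests that probe the
  stopband trim ≥ 10 s per edge;
- repeat-filtering an already broadband-filtered signal changes RMS by
  ≈ 2%; repeat-filtering a narrow rhythm through its own band filter
  changes RMS by 5–6% (transition-band energy is a larger fraction of a
  narrow band), so "filtering is idempotent" should only be relied on for
  the broadband step.

ICA-based artifact removal is deliberately out of scope: the synthetic data
are artifact-free, and real-data users are expected to supply cleaned
signals.

## Feature conventions

**Relative power.** Computed from the one-sided periodogram of the
*broadband* window (not the band-filtered time series): the defining ratio
uses a single spectrum with a shared denominator.  Spectral integration is
a plain bin sum on the DFT grid `k·fs/N`.  Bins are assigned to bands by
half-open intervals `[f_lo, f_hi)` — including the upper analysis bound, so
the bin at exactly 45 Hz is excluded.  This makes two identities exact on
edge-aligned grids (4-s windows at 128 Hz): a flat spectrum scores RP = 1
in every band, and the bandwidth-weighted RP sum equals 1 for every window.
Closing the last band at 45 Hz would add one bin and break the first
identity; the energy there is negligible after the broadband filter.  The
periodogram is normalized so its bins sum to the window's mean square
(discrete Parseval identity); any constant normalization cancels in RP.

**Fuzzy entropy.** Subsequences are mean-centered *per subsequence* at both
dimensions m and m+1 (the standard convention; the defining equations
leave the baseline ambiguous).  Dimension m uses N−m subsequences and
dimension m+1 uses N−m−1, following the defining sums literally.  The
tolerance is r = k·δ with k = 0.2 and δ the per-window, per-channel
standard deviation, making FuzEn exactly invariant to positive rescaling.
The O(N²) pair sum is numba-compiled; membership terms below 1e-22 are
skipped, an error 12 orders of magnitude under the 1e-10 oracle-equivalence
tolerance used in tests.  With per-subsequence centering FuzEn ≥ 0 is not a
theorem, but it holds on all tested signal classes.

**Phase lag index.** Instantaneous phases come from the analytic signal of
the *whole window*; phase differences are wrapped to (−π, π]; sign(0)
contributes exactly 0, so identical signals give PLI = 0 exactly, with or
without trimming.  By default 5% of samples at each window edge are
excluded from the sign average (finite-window Hilbert edge distortion); the
fraction is configurable and the PLI = 0 / PLI = 1 analytic cases hold at
any trim.  PLI matrices are symmetric with zero diagonal; the upper
triangle is flattened in row-major channel order.

**Canonical column order.** Family-major (RP, FuzEn, PLI), band-major
within family (Delta → Gamma), site order within band (montage channel
order; pairs `(i, j)` with i before j in montage order, named
`PLI_<band>_<chA>-<chB>`).  Feature counts for the default montage:
80 + 80 + 600 = 760.

**Degenerate windows.** A window with a constant channel or zero total
power drops as a whole row (logged, listed in `table.attrs["dropped"]`);
imputation would silently bias group comparisons.

## Classification

Stratified k-fold cross-validation (default 10) with two split units:

- `window` (default): rows split independently.  Windows of one subject can
  appear in both training and test folds, so accuracy is optimistic
  whenever subjects have idiosyncratic signatures.  This mirrors common
  practice in window-level EEG classification and is the default for
  comparability.
- `subject`: all windows of a subject stay in one fold
  (StratifiedGroupKFold); leakage-safe, recommended for real inference.

SCZ is the positive class for precision/recall/F1 (a choice this package
fixes; the convention is often left unstated).  Metrics are computed
directly from confusion counts and reported as mean ± sd over folds on the
percent scale.  Folds are stratified because the window-level design is
class-imbalanced whenever group sizes differ.

**Model registry.** The four conventional learners resolve to their
libraries when installed and otherwise to scikit-learn stand-ins:

| name     | native library            | stand-in                        |
|----------|---------------------------|---------------------------------|
| rf       | (scikit-learn)            | RandomForestClassifier          |
| xgboost  | xgboost.XGBClassifier     | GradientBoostingClassifier      |
| catboost | catboost.CatBoostClassifier | HistGradientBoostingClassifier |
| lightgbm | lightgbm.LGBMClassifier   | HistGradientBoostingClassifier  |

Hyperparameters are library defaults plus a fixed seed; `ModelConfig`
accepts overrides but the package tunes nothing.  Swapping learners changes
scores only — fold structure, table handling and metric code are shared.

## Feature selection

Default: a single importance ranking from the base model, averaged over the
CV folds' fitted models (descending, ties broken by canonical column
order), followed by cross-validated accuracy on nested ranking *prefixes*
of growing size.  The optimal size is the accuracy argmax with ties broken
toward the smaller subset (parsimony).  A `stride` parameter evaluates
every s-th size for tractability; the full feature count is always
included, and because a feature subset is treated as a set (canonical
column order preserved inside the model matrix) the last curve point
reproduces the full-feature CV accuracy exactly.

`elimination_ranking` provides the stricter recursive variant — re-fit and
re-rank after eliminating the `step` least important features each round —
for users who want re-scoring semantics; it is far more expensive at 760
features and feeds the same curve.

Importances are the estimator's native `feature_importances_` when exposed;
for estimators without them (the HistGradientBoosting stand-in) the package
falls back to held-out permutation importance (default 3 repeats per fold),
clipped at zero so that scores are non-negative.

## Synthetic cohorts

`simulate_cohort` draws per-subject recordings from sub-seeds derived
deterministically from the master seed.  Each channel is a sum over the
five bands of unit-variance band-limited noise (filtered with the *same*
filters as the analysis, avoiding generation/analysis band mismatch),
scaled by a baseline per-band RMS amplitude — Delta 20, Theta 10, Alpha 15,
Beta 5, Gamma 2 in arbitrary units, a coarse 1/f-like resting profile with
the usual alpha prominence — plus independent white sensor noise
(sd 2.0).  No microvolt calibration is attempted; every downstream feature
is scale-invariant or ratio-based.

Planted group effects, all applied to the SCZ group:

- **band_power_shift** — multiplicative per-band amplitude factor; defaults
  Delta/Theta/Beta 1.3 and Alpha/Gamma 0.7, the direction pattern reported
  for pediatric SCZ.
- **regularity_gain** — a fraction g of the band variance is replaced by a
  deterministic sinusoid (√(1−g)·noise + √g·tone, variance preserved);
  defaults 0.5 in Theta/Alpha/Beta/Gamma and 0 in Delta.  The tone sits at
  the *lower quarter* of the band (f_lo + 0.25·width): measured on this
  pipeline, a tone at the band center *raises* FuzEn at moderate gains —
  beating between the tone and the surviving band noise adds short-range
  irregularity — and only lowers it once g ≳ 0.8, whereas the lower-quartile
  tone lowers FuzEn monotonically for g ≥ 0.5 in Delta–Beta.  In Gamma
  (30–45 Hz at 128 Hz, ≈ 4 samples per cycle) the reduction stays marginal
  at g = 0.5; this is a known generator limitation, and recovery tests
  target the lower bands.
- **coupling_edges** — per edge, a shared unit-variance band-limited source
  is injected into channel i and a delayed copy into channel j, each with
  weight `amp·√(c/(1−c))` so the injected fraction of band variance is the
  coupling strength c.  The delay is the integer sample count closest to
  the requested phase lag at the band center, clamped to ≥ 1 sample (a
  sub-sample lag at high frequencies would otherwise round to zero and be
  invisible to PLI).  Defaults: ten edges at lag π/2 — coupling 0.6 vs 0.0
  raising Theta/Beta/Gamma PLI and lowering Alpha PLI in SCZ, matching the
  reported direction pattern.

`EffectSpec.neutral()` removes every effect, making HC and SCZ draws from
one distribution (with identical generator state the two groups are
bit-identical) — the null cohort for chance-level checks.

Defaults emulate the reference study design: 39 HC + 45 SCZ, 60 s at
128 Hz, so 4-s segmentation yields 15 windows per subject and 1,260 rows
(585 HC / 675 SCZ).  The 60-s duration is inferred from those window
counts (the design itself states no recording length) and remains
configurable.

**What a green test does not establish.**  The generator produces
stationary, artifact-free, Gaussian-mixture signals with linear coupling.
It does not emulate blinks/EMG, volume conduction, non-stationarity,
inter-subject amplitude variability beyond seeding, age/sex covariates, or
1/f spectral slopes within bands.  Recovery tests therefore validate the
*estimators and plumbing*, not clinical effect sizes; classification
accuracies on synthetic cohorts say nothing about real-data performance.

## Runtime

Fuzzy entropy dominates extraction cost (~3 ms per 512-sample window per
channel per band after numba compilation; ≈ 100,800 evaluations ≈ 5 min for
the full 84-subject table on one CPU).  Acceptance-scale recovery runs use
20+20 subjects × 32 s, and selection curves use stride > 1; both choices
are runtime management, not tuning.

## Known limitations

- Window-level CV (the default, for comparability) leaks subject identity;
  use `unit="subject"` for honest generalization estimates.
- The gamma-band regularity effect is weak at moderate gains (above).
- EDF input requires the optional `mne` dependency; the supported exchange
  format is a plain-text samples × channels matrix with a channel header
  plus a cohort manifest CSV.
- RP bins are exact only on edge-aligned DFT grids (window length × band
  edges commensurate); for other window lengths the half-open bin
  assignment is still consistent (no double counting) but the flat-spectrum
  RP = 1 identity holds only approximately.
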