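# Methods

`icpforecast` replicates, end to end, an early-warning modeling study for
intracranial hypertension (IH) after traumatic brain injury: features are
extracted from the first 6 h of intracranial-pressure (ICP) monitoring and
used to predict whether a qualifying hypertensive event occurs later in the
monitoring period.  Because the patient recordings behind such studies are
not publicly shareable, the package pairs the analysis pipeline with a
synthetic cohort generator whose ground truth is planted, so every stage is
testable against known answers.

## Outcome definitions

An IH event is epoch-mean ICP strictly above 22 mmHg sustained strictly
longer than 5 min; a severe IH (SIH) event is the same excursion sustained
longer than 1 h.  Both inequalities are strict, and a single sub-threshold
or invalid epoch terminates a run — no gap tolerance is applied, because
none is defined clinically.  Outcomes are assessed only on the monitoring
period after the 6-h feature window; an episode counts if any part of it
lies after hour 6.  Event detection runs on the unsmoothed 12-s epoch
means: the causal smoothing filter used for feature extraction delays the
threshold crossing by several epochs, and the outcome is defined on ICP
itself, not on a filtered feature series.

## Signal preparation

Raw 1-Hz channels (ICP, mean arterial pressure MAP, ICP pulse amplitude
AMP) are averaged over non-overlapping 12-s epochs, which suppresses pulse
and respiratory waves and leaves the slow ICP dynamics.  A span-4 moving
average then removes sharp noise.  The window is trailing (causal) with a
shortened leading edge — an even-length centered window is ill-defined, and
a causal filter guarantees the 6-h feature window contains no future
information.  Cerebral perfusion pressure is derived from the smoothed
series as CPP = MAP − ICP.  Epochs with more than 50% missing samples are
invalid and propagate as such; downstream consumers skip rather than
interpolate them.  When only a pulse-resolved ICP waveform is available,
AMP is recovered by band-passing the cardiac band (0.66–3 Hz) and taking
the peak-to-trough excursion per 10-s window; the cohort simulator emits
AMP directly at 1 Hz, since the analysis itself suppresses pulse waves.

## Features

Eleven features per patient: age, sex (0 = female, 1 = male), admission
GCS; the 6-h means of ICP, CPP, PRx and RAP; and the sample entropy and
Lempel–Ziv complexity of the 6-h ICP and CPP epoch series.

* **PRx** (cerebral autoregulation) is the moving Pearson correlation of
  ICP and MAP; **RAP** (cerebrospinal compensatory reserve) the moving
  Pearson correlation of AMP and ICP.  The correlation window is 30 epochs
  (6 min) — the neuromonitoring convention of ~30 samples per window — with
  a stride of one epoch; windows containing an invalid epoch, or with zero
  variance in either channel, yield invalid values.  Window means average
  the valid values only.
* **SampEn(m=2, r=0.2·SD)** uses the Chebyshev norm, excludes self-matches,
  and counts both template lengths over the N−m offsets (the
  Richman–Moorman convention).  A constant series returns 0; if no m-match
  extends to m+1, +inf.  The tolerance r is computed from the SD of the
  analysed 6-h window itself, which makes the statistic invariant to affine
  rescaling.
* **LZc** is the LZ76 exhaustive-parsing phrase count of the binarized
  series (median split by default; mean split available), reported
  normalized as c(n)·log₂(n)/n so long equiprobable random strings approach
  1.  On ~1800-epoch windows the normalized values of realistic series fall
  in the 0.05–0.4 range.

Missing features are kept as missing in the cohort table; the modeling
stage imputes them with training-partition medians.

## Cohort inclusion

Three exclusion rules, each with a machine-readable reason code: recordings
shorter than 18 h (`short_recording`); more than 30% invalid epochs
(`artifact`); and persistent early hypertension, operationalized as
first-6-h mean ICP > 22 mmHg *and* more than 80% of first-6-h epochs above
22 mmHg (`early_persistent_ih`).  The last two thresholds are this
package's own operationalizations of qualitative clinical criteria and are
configuration-exposed.

## Modeling workflow

For each task (IH, SIH): a seeded stratified 70/30 split; recursive feature
elimination with cross-validation (RFE-CV) on the training partition; a
variance-inflation-factor screen of the selected set (VIF_j = 1/(1−R²_j),
flag threshold 5); a hyperparameter grid search (mtry ∈ {1, 2, 3, ⌊√p⌋+1},
minimum leaf size ∈ {1, 5, 10}) scored by mean inner 5-fold CV AUC; a final
random-forest refit with out-of-bag (OOB) scoring; and a classification
cutoff maximizing Youden's J = sensitivity + specificity − 1 on the
*training* OOB probabilities.  No quantity fitted anywhere in the workflow
sees the test partition.

RFE drops one feature per iteration, ranked by permutation importance
measured on the held-out inner folds (accuracy drop when one feature is
shuffled in the validation fold, averaged over folds) — the Mean Decrease
Accuracy criterion computed out-of-sample.  The retained set size maximizes
mean inner-CV AUC, ties going to the smaller set.

Forests default to 100 trees.  This is deliberately below the several
hundred often used for final reporting: the workflow refits forests
~10³ times (RFE steps × folds × grid cells × CV repetitions), and at
n ≈ 200 patients the OOB AUC is insensitive to forest size (a test asserts
|ΔAUC| < 0.03 between 500 and 1000 trees and < 0.05 between 100 and 500);
`RFConfig(n_trees=...)` raises it when wanted.

All threshold logic uses the strict rule *predicted positive iff score >
cutoff*; ROC points, the Youden scan and the confusion metrics share this
convention, so the chosen cutoff reproduces exactly the metrics reported at
it.  AUC is the trapezoid over all thresholds, which equals the
Mann–Whitney pair statistic with ties counted one half (asserted against an
O(n²) oracle).  Fivefold cross-validation re-runs the *entire* workflow —
imputation, RFE-CV, grid search, cutoff — inside each training split, and
runs on the whole included cohort as a separate analysis from the 70/30
evaluation; both are reported.

Reported importances are Mean Decrease Accuracy (per-tree OOB permutation)
and Mean Decrease Gini (unnormalized impurity decrease averaged over
trees).  Group-comparison tables use Shapiro–Wilk at α = 0.05 in both
groups to route continuous variables to the t test (normal) or
Mann–Whitney U (otherwise); binary variables use the chi-square test.

## The synthetic cohort generator

Each patient's channels are generated at 1 Hz for 24 h:

    ICP = ceil( b_icp + a_L·L(t) + a_B·s(t) + σ_icp·f(t) ) + episode(t)
    MAP = b_map + a_M·( ρ·ẑ(t) + √(1−ρ²)·ẑ'(t) ) + σ_cpp·g(t)
    AMP = b_amp + k·(ICP − b_icp) + σ_amp·e(t)

* **L(t)** is a plateau-level process: unit-SD levels held for an
  exponential dwell (~13–30 min) with 5-min smoothed transitions.  This
  reproduces the locally flat, occasionally shifting character of slow ICP,
  which is what keeps the epoch-series SampEn (~0.04–0.12) and normalized
  LZc (~0.08–0.15) in the clinically reported range — stationary AR
  processes alone cannot get SampEn that low at 12-s epochs.
* **s(t)** is B-wave-band AR(1) noise (τ = 60 s) and **f(t), g(t)** are
  short-memory AR(1) processes (τ = 15 s); their amplitudes control the
  complexity of the ICP and CPP epoch series.
* **ẑ(t)** is the standardized ICP slow part; sharing it with MAP at weight
  ρ makes the slow-band ICP–MAP correlation — hence PRx — equal ρ up to
  dilution by the unshared fast noise.
* **ceil(·)** is a softplus ceiling at 21.5 mmHg: background ICP saturates
  just below the 22-mmHg threshold, so only planted episodes can cross it.
  This guarantees exact planted labels and makes the early-persistent-IH
  exclusion inert by construction.
* **episode(t)** is a trapezoid to a fixed 29-mmHg plateau with 2-s ramps
  placed so ICP crosses 22 mmHg at exactly the planted onset and again at
  onset + duration; background variability is damped 4× during the episode
  (plateau waves suppress variability), so an episode is never fragmented
  by noise.  IH episodes last 8–30 min, SIH episodes 70–150 min, with
  onsets drawn log-normally after hour 6 (median latencies ≈ 9.8 h and
  11.2 h past the feature window, matching the reported event timing).

Group structure: outcome flags are Bernoulli (62.3% IH; 70% of IH progress
to SIH).  Effect sizes are graded negative → mild IH → SIH and drawn per
patient around the group mean (baseline ICP 9 / 10.5 / 14 mmHg with 4 mmHg
between-patient SD, truncated to [4, 17]; PRx coupling 0.18 / 0.30 / 0.68 ±
0.12; CPP fast-noise scale 0.50 / 0.58 / 0.85 and ICP fast-noise scale 0.10
/ 0.07 / 0.025 with 0.35 log-SD; MAP baseline N(88, 9) mmHg independent of
outcome).  These values were calibrated once so that a 200-patient cohort
reproduces the reported group *contrast directions* and dispersion —
positives: higher ICP, PRx, CPP-SampEn, CPP-LZc; lower GCS and ICP-LZc;
older and lower-GCS in SIH — with realistic overlap between groups, not to
match any cohort's absolute numbers.  Demographics: age ~N(50/54/59, 12),
GCS ~round N(9 / 7.2 / 6.8, 2.4) clipped to [3, 15], two-thirds male.

Determinism: one master seed; each patient's stream is keyed by
(seed, CRC32(patient_id)), so cohort composition is invariant to generation
order and byte-identical across runs.

### What the generator does and does not emulate

It emulates: slow ICP dynamics at the epoch scale, group effect directions
and dispersions, threshold-duration events with known onsets, and the
cohort prevalences.  It does not emulate: pulse-resolved waveform
morphology (AMP is generated directly from its coupling to ICP), treatment
responses and censoring, artifacts and missing spans, circadian structure,
or the joint dependence structure of real features — in particular, the
generator cannot dissociate sample entropy from Lempel–Ziv complexity as
sharply as real data does, so ICP-SampEn separates the groups more strongly
in synthesis than in the reported cohort, and model AUCs on synthetic
cohorts are optimistic relative to the published ones.  Passing tests
therefore demonstrate the correctness of the pipeline's computations and
its ability to recover planted structure, not clinical performance.

## Numerical choices and degenerate inputs

* Moving correlations: windows with any invalid epoch or zero variance are
  invalid; values clipped to [−1, 1] against floating-point overshoot.
* SampEn: tolerance from the window's own SD; constant series → 0; no
  extending match → +inf.
* Binarization: all-equal series binarizes to all zeros with a warning.
* Youden ties resolve to the lowest cutoff; the all-positive operating
  point is represented by (min score − 1) so the strict ">" rule realizes
  it exactly; fitted cutoffs are clipped into [0, 1].
* F1 is defined as 0 when precision or recall is undefined or both are 0.
* Exact collinearity reports VIF = +inf.
* Stratified inner folds are re-drawn once if a fold comes out
  single-class, then error.
* Grid-search ties resolve to the first combination in (mtry, min-node)
  order; RFE set-size ties resolve to the smaller set.

## Problem sizes

The default study simulates 200 patients × 24 h at 1 Hz (~86 k samples ×
3 channels each), yielding 1800-epoch feature windows; the full two-task
study (outer evaluation plus fivefold CV with the complete workflow inside
each fold) runs in a few minutes on one CPU.  The acceptance script
(`scripts/acceptance.py`) uses exactly this cohort size.

## Known limitations

* The correlation window length (30 epochs), binarization rule (median),
  LZc normalization, and the artifact/persistent-IH operationalizations are
  conventional choices where the underlying study design leaves them
  unstated; all are configuration-exposed.
* The fivefold CV is run on the whole included cohort by default (the
  alternative — training partition only — is available by passing that
  partition), so its folds overlap the 70/30 test set across analyses.
* RAP is simulated with a single coupling constant for all groups; the
  compensatory-reserve physiology it proxies is not modeled.
* Between-feature dependence in the generator arises only through shared
  signal components; real cohorts have richer covariance.
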