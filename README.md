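# icpforecast

Early prediction of intracranial hypertension from the first hours of
intracranial-pressure monitoring.

After severe traumatic brain injury (TBI), intracranial pressure (ICP) is
monitored invasively and treated once it exceeds 22 mmHg. Treatment today is
reactive; a model that flags, from the *first 6 h* of monitoring, which
patients will go on to develop intracranial hypertension (IH: ICP > 22 mmHg
for > 5 min) or severe IH (SIH: > 1 h) would let clinicians escalate
prophylactically. `icpforecast` implements that workflow end to end for
researchers in neurocritical-care data analysis:

* **Signal preparation** — 12-s epoch averaging (suppressing pulse and
  respiratory waves), span-4 causal smoothing, CPP = MAP − ICP.
* **Linear cerebrovascular indices** — the pressure reactivity index
  PRx = moving r(ICP, MAP) and the compensatory reserve index
  RAP = moving r(AMP, ICP), over 30-epoch (6-min) windows.
* **Nonlinear complexity features** — sample entropy SampEn(m = 2,
  r = 0.2·SD) and normalized Lempel–Ziv complexity (LZ76, exhaustive
  parsing of the median-binarized series) of the ICP and CPP epoch series.
* **Outcome labeling** — strict threshold-duration episode detection on the
  post-6-h monitoring period, plus cohort inclusion filters (≥ 18 h of
  recording, ≤ 30% invalid epochs, no persistent early hypertension).
* **Modeling** — per task (IH, SIH): stratified 70/30 split, random-forest
  recursive feature elimination with cross-validation (RFE-CV), variance
  inflation factor screen, hyperparameter grid search, Youden-index cutoff
  from training out-of-bag probabilities, held-out test metrics
  (accuracy/sensitivity/specificity/recall/F1/AUC), fivefold
  cross-validation of the whole workflow, and Mean Decrease
  Accuracy / Gini importances.
* **Synthetic cohorts** — because such patient recordings are not public,
  a simulator generates cohorts with planted IH/SIH episodes, tunable
  ICP–MAP coupling (controls PRx), tunable irregularity (controls
  SampEn/LZc) and realistic between-patient spread, so every stage is
  testable against known ground truth. See `docs/methods.md` for the signal
  model and its limits.

## Worked example

```python
import numpy as np
from icpforecast import (
    SimConfig, GroundTruth, simulate_patient, preprocess, extract_window,
    prx, rap, window_mean, complexity_features, resample_epochs, label_outcomes,
)

cfg = SimConfig(n_patients=1, seed=7)
truth = GroundTruth("P0001", is_ih=True, is_sih=False,
                    planted_onset_hours=10.0, planted_duration_min=12.0)
rec = simulate_patient(cfg, "P0001", truth)

es6 = extract_window(preprocess(rec), 0, 6)       # first-6-h feature window
print("ICP_m  %.2f mmHg" % window_mean(es6.icp))
print("PRx_m  %.3f" % window_mean(prx(es6).values))
print("RAP_m  %.3f" % window_mean(rap(es6).values))
print({k: round(v, 3) for k, v in complexity_features(es6).items()})

label = label_outcomes(resample_epochs(rec))      # post-6-h outcome
print(label.ih, label.sih, "time to IH %.2f h" % label.time_to_ih_h)
```

prints

```
ICP_m  9.54 mmHg
PRx_m  0.161
RAP_m  0.026
{'icp_sampen': 0.11, 'cpp_sampen': 0.294, 'icp_lzc': 0.12, 'cpp_lzc': 0.138}
True False time to IH 4.00 h
```

— a mild-IH patient: 6-h mean ICP well under the 22-mmHg threshold, a
positive PRx (impaired autoregulation), complexity values in the clinically
reported range, and the planted episode at hour 10 recovered as an IH (not
SIH) outcome 4 h after the feature window closes.

The full study replica — simulate a cohort, filter, featurize, label,
train and evaluate both models — is one call (or
`icpforecast run-study --seed 42 --out bundle/` from a shell):

```python
from icpforecast import RunConfig, run_study
bundle = run_study(RunConfig().with_seed(42), out_dir="bundle")
```

which writes the feature table, labels, group-comparison tables, VIF
tables, per-task cross-validation summaries, importances, fitted models,
and a manifest (config hash, seed, versions) into `bundle/`.

## Command line

```
icpforecast simulate  --seed 1 --out cohort/       # recordings + cohort.csv
icpforecast featurize --cohort cohort/ --out features.csv
icpforecast label     --cohort cohort/ --out labels.csv
icpforecast train     --features features.csv --task sih --out model.joblib
icpforecast evaluate  --features features.csv --model model.joblib --out eval/
icpforecast run-study --seed 42 --out bundle/
```

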