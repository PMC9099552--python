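# vbreath — a virtual breathalyzer from paired free-gait sensor data

`vbreath` detects alcohol intoxication from the way a person walks. It
compares two short free-walking sessions recorded by body-worn motion
sensors — a sober **baseline** and a later **suspect** session — and
classifies the *change* between them. Ground truth is the suspect
session's breath alcohol concentration (BrAC, µg/L of breath),
thresholded at 220, 240, or 380 µg/L.

The key idea is the before/after difference representation. Each session
is reduced to a fixed 228-feature vector (12 channels × 19 features),
and the classifier input is `f_suspect − f_sober`, elementwise. Stable
personal gait traits cancel in the difference; what remains are the
known motor signatures of intoxication — slower cadence, decreased
acceleration, increased low-frequency postural sway, and more irregular
movement. A synthetic cohort generator with a controllable effect size
lets the whole pipeline be exercised and evaluated end to end without
real recordings.

See [docs/methods.md](docs/methods.md) for the full model, feature
definitions, generator parameters, and evaluation caveats.

## Package layout

| Module | Contents |
|---|---|
| `vbreath.signal_model` | channel recordings, sessions, windowing, CSV/manifest I/O |
| `vbreath.features` | the four feature families and the 228-feature canonical vector |
| `vbreath.pipeline` | difference vectors, BrAC labeling, the five classifiers, `is_intoxicated` |
| `vbreath.evaluation` | leave-one-user-out CV, AUC, operating-point policies, ablations |
| `vbreath.simulate` | synthetic paired cohort with a dose-dependent intoxication transform |
| `vbreath.cli` | `vbreath simulate / extract / train / predict / evaluate / ablate` |

## Worked example (Python API)

```python
from vbreath import (SimConfig, simulate_cohort, build_dataset, leave_one_user_out,
                     DetectionModel, EstimatorKind, is_intoxicated)
from vbreath.pipeline import instances_to_matrix

# a 30-subject cohort with a strong dose effect
cohort = simulate_cohort(SimConfig(n_subjects=30, effect_size=3.0, seed=42))
instances = build_dataset(cohort, threshold=240.0)
n_pos = sum(i.label.value == "intoxicated" for i in instances)
print(f"{len(instances)} difference instances, {n_pos} intoxicated at BrAC >= 240")

# leave-one-user-out evaluation
result = leave_one_user_out(instances, "adaboost", seed=0)
print(f"LOOCV AUC: {result.auc:.3f}")
print(f"FPR at TPR=1: {result.policy_fpr_at_full_tpr:.3f}")
print(f"TPR at FPR=0: {result.policy_tpr_at_zero_fpr:.3f}")

# train on everyone and query one subject
X, y, _ = instances_to_matrix(instances)
model = DetectionModel(EstimatorKind.ADABOOST, seed=0).fit(X, y)
pair = max(cohort, key=lambda p: p.sample_after.brac)
print(f"subject {pair.subject_id}: BrAC {pair.sample_after.brac:.0f} ->",
      is_intoxicated(model, pair.sample_before, pair.sample_after))
```

Output:

```
30 difference instances, 10 intoxicated at BrAC >= 240
LOOCV AUC: 0.900
FPR at TPR=1: 1.000
TPR at FPR=0: 0.800
subject S011: BrAC 472 -> True
```

(`FPR at TPR=1` is the false-alarm cost of a never-miss-anyone policy;
one stubborn low-scoring positive makes it expensive even when the AUC
is high. `TPR at FPR=0` is the detection power of a
never-falsely-accuse policy.)

## Worked example (CLI)

```bash
vbreath simulate --n 12 --effect-size 3.0 --seed 7 --out demo/cohort
# wrote 24 session manifests under demo/cohort

vbreath extract --manifests demo/cohort --out demo/features.csv
# wrote 24 sessions x 228 features to demo/features.csv

vbreath train --features demo/features.csv --threshold 240 --model adaboost --out demo/model.bin
# trained adaboost on 12 instances -> demo/model.bin

vbreath evaluate --features demo/features.csv --threshold 240 --model adaboost
# adaboost @ BrAC>=240: AUC=0.812 FPR@TPR=1 1.000 TPR@FPR=0 0.000

vbreath predict --model demo/model.bin \
    --before demo/cohort/S001/before/manifest.json \
    --after  demo/cohort/S001/after/manifest.json
# score=0.8808 threshold=0.5 intoxicated=True   (S001's BrAC is 246)
```

`vbreath ablate --by device|sensor|family --mode only|all_except`
re-runs the evaluation on feature subsets (e.g. wrist-only, or
everything except the spectral family).

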