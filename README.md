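# ordvert

Ordinal-regression losses for vertebral-level classification on CT-like image
series, built around the **ordinal residual dual loss (ORDL)**.

## The problem

Identifying which vertebral level (T12, L1, L2, L3, L4) an axial CT slice
shows is a prerequisite for automated sarcopenia assessment, which measures
muscle mass at L3. The levels are *ordered*: calling an L4 slice "T12" is a
worse mistake than calling it "L3", but plain cross-entropy charges both
errors identically. `ordvert` is for researchers comparing training
objectives that respect that order — it implements the ORDL objective, the
standard baselines (class-distance-weighted CE, CORN, a CORAL reference
head), the evaluation metrics, a patient-grouped cross-validation harness,
and a seeded synthetic generator of vertebral-series-like image cohorts so
the whole pipeline runs without private hospital data.

## The loss

For true class c among N ordered classes, define the linearly decaying target
profile

    O_i = 1 − |i − c| / (N − 1)          (peak 1 at c, 0 at distance N − 1)

and residuals d_i = P_i − O_i against the predicted probabilities P. Then

    ORL(P, c)  = − Σ_i log(1 − |d_i|)
    ORDL(P, c) = CE(P, c) + λ · ORL(P, c),    λ = 1 by default.

Mass placed far from the true class violates the decaying profile and is
penalised increasingly hard — without the hand-tuned distance exponent that
class-distance-weighted CE requires.

## Worked example

```python
import numpy as np
from ordvert import (
    SyntheticConfig, generate_cohort, export_cohort, read_manifest,
    patient_split, kfold_by_patient, TrainConfig, compare_methods, load_dataset,
    ordinal_residual_dual_loss, cross_entropy,
)

# the loss itself: a near-miss beats a far-miss under ORDL, not under CE
near = [0.05, 0.55, 0.35, 0.05]   # mass leaks to the neighbour of c=1
far  = [0.05, 0.55, 0.05, 0.35]   # same mass leaks three ranks away
print(cross_entropy(near, 1), cross_entropy(far, 1))
# 0.5978370007556204 0.5978370007556204        <- CE cannot tell them apart
print(ordinal_residual_dual_loss(near, 1), ordinal_residual_dual_loss(far, 1))
# 2.868441289850523 3.1301818124135243         <- ORDL penalises the far miss

# a full (desk-scale) experiment on synthetic data
cohort = generate_cohort(SyntheticConfig(n_patients=40, seed=0))
manifest = export_cohort(cohort, "dataset")
data = load_dataset(read_manifest("dataset/manifest.csv"), (32, 32))
plan = patient_split(manifest, ratio=0.8, seed=0)       # 32 train / 8 test patients
plan.folds = kfold_by_patient(plan.train_patient_ids, k=10, seed=0)
report = compare_methods(data, plan, [
    TrainConfig(loss_name="ce", max_epochs=120, seed=0),
    TrainConfig(loss_name="ordl", max_epochs=120, seed=0),
])
print(report.to_markdown())
```

which prints a benchmark table of per-fold means ± SD,

```
| Method | Accuracy | F1-Score | MAE | RMSE | QWK |
|---|---|---|---|---|---|
| ce | 0.7643 ± 0.076 | 0.7616 ± 0.077 | 0.2357 ± 0.076 | 0.4797 ± 0.079 | 0.9416 ± 0.019 |
| ordl | 0.7438 ± 0.074 | 0.7415 ± 0.076 | 0.2562 ± 0.074 | 0.5014 ± 0.073 | 0.9364 ± 0.019 |

Primary contrast ce vs ordl (Welch t-test on fold accuracies): t = 0.6144, df = 17.99, p = 0.5466
```

accuracy/F1 around 0.75 (chance 0.2), quadratic weighted kappa above 0.93
(the predictions that miss almost always land on an adjacent level), and the
pre-specified Welch t-test on the paired fold accuracies. At this desk scale
— a tiny CNN on one small synthetic cohort — the CE-vs-ORDL difference is
well within fold noise and the test correctly reports no significant gap;
the value of the harness is the protocol (paired folds, per-fold metrics,
training curves, NaN flags), which supports the same analysis at any scale.

The same pipeline is scriptable from a shell:

```bash
ordvert simulate --out dataset --n-patients 40 --seed 0
ordvert split --manifest dataset/manifest.csv --ratio 0.8 --k 10 --seed 0 --out plan.json
ordvert compare --manifest dataset/manifest.csv --plan plan.json \
    --losses ce,ordl,cdw_ce:a=2,corn --max-epochs 120 --out report.json
ordvert report --in report.json --format md
```

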