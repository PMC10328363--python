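# stiffindex

Normalized arterial-stiffness scoring and decision-tree rule mining for
hypertensive cohorts.

## The problem

The finger-photoplethysmography arterial stiffness index (ASI, m/s; the
participant's height divided by the pulse transit time) has no accepted
normal reference range, so a raw ASI value carries little individual
meaning. `stiffindex` implements the normalization-and-classification
workflow that turns it into an interpretable score:

1. **Reference equation.** In a "healthy" cohort (no hypertension,
   diabetes, prior cardiovascular event or chronic kidney disease), fit by
   ordinary least squares

   `predictedASI = b0 + b_age·age + b_sex·sex + b_MBP·meanBP + b_HR·HR`

   with sex coded male = 1 / female = 0 and mean BP = (SBP + 2·DBP)/3 on
   the device-adjusted scale.

2. **Stiffness index.** For each hypertensive participant (without prior
   CV events), the normalized score

   `index = (measuredASI − predictedASI) / predictedASI`,

   with `index > 0` defining increased arterial stiffness.

3. **Classifier screening.** Blood biomarkers (ALT, AST, albumin, HDL,
   triglycerides, urate, phosphate, cystatin C, testosterone, smoking
   pack-years) are screened by univariate tests (Student t / Pearson χ²),
   then a forward-backward logistic regression (likelihood-ratio entry and
   stay at p < 0.05) retains the independent classifiers, and each gets an
   optimal cutpoint by maximizing the Youden index J = Se(c) + Sp(c) − 1.

4. **Rule mining.** A CART (Gini impurity, binary splits, cost-complexity
   pruning with the penalty chosen by cross-validation) is grown on the
   threshold-binarized classifiers; root-to-leaf paths with at least 20
   participants and a positive-index rate above 70% are reported as
   clinical rules. Tree vs logistic discrimination is compared with the
   DeLong test for correlated ROC curves.

The original study population (a large UK population survey) is
access-controlled, so the package ships a seeded synthetic cohort
generator calibrated to the published population moments; every stage of
the pipeline runs, and is tested, on data it generates itself.

## Worked example

```python
import stiffindex as si
from stiffindex.tree import CartParams
from stiffindex.pipeline import report

cfg = si.interaction_demo_config(n_reference=5_000, n_hypertensive=20_000, seed=7)
si.run_pipeline(cfg, "out", cart=CartParams(seed=7))
print(report("out"))
```

prints (abridged):

```
Reference model (predicted ASI, m/s):
  age = 0.07962657632938655 (se 0.004620535299333868)
  sex = 1.0525465369440516 (se 0.07497510646122581)
  mean_bp = 0.04404790161884705 (se 0.006785717463720057)
  hr = 0.016035708478438597 (se 0.003719981329302499)

Retained classifiers (by sensitivity at the Youden cutpoint):
  hdl >= 1.067  Se=0.840 Sp=0.187 AUC=0.519
  triglycerides >= 1.282  Se=0.698 Sp=0.331 AUC=0.516
  ...

Retained decision rules: 3
  Rule 1: if alt >= 25.55, phosphate >= 1.216, albumin > 45.52,
          hdl < 1.067, pack_years >= 2.59 -> N=83, 77.1% positive
  ...

Model comparison (in-sample): tree AUC 0.605 vs logistic AUC 0.565,
DeLong p = 7.05e-20
```

Reading the output: the fitted reference coefficients recover the
generating equation (each within sampling error of the configured values,
e.g. 0.0796 vs 0.0837 m/s per year for age at this modest n); each
retained classifier is shown with its oriented Youden cutpoint,
sensitivity, specificity and single-variable AUC; the retained rules are
subgroups whose positive-stiffness rate clears the 70% floor with at
least 20 members; and under the interaction-bearing demonstration
conditions the tree discriminates better than the main-effects logistic
model (DeLong p ≪ 0.05). The same pipeline is available from the shell:

```sh
stiffindex run-all --seed 7 --n-reference 5000 --n-hypertensive 20000 --outdir out
stiffindex report --outdir out
```

## Layout

- `stiffindex.simulate` — seeded two-arm synthetic cohort generator
- `stiffindex.preprocessing` — device BP adjustment, CKD-EPI eGFR,
  diagnostic flags, outlier exclusion, cohort selection
- `stiffindex.reference` — `ReferenceASIModel` (OLS) and the stiffness index
- `stiffindex.screening` — univariate screen, `StepwiseLogistic`,
  ROC/AUC, Youden thresholds
- `stiffindex.tree` — `GiniTreeClassifier`: CART growth, cost-complexity
  pruning, repeated cross-validation, rule extraction
- `stiffindex.evaluation` — confusion metrics, DeLong test, collinearity
- `stiffindex.pipeline` / `stiffindex.cli` — orchestration and the
  `stiffindex` command

See `docs/methods.md` for the statistical methods and their assumptions.
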