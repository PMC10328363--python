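# Methods

This note documents the statistical procedures implemented in
`stiffindex`, the synthetic data they are exercised on, the numerical
choices made where a procedure is under-determined, and what the tests do
and do not establish.

## Measurement model and preprocessing

Automated-device blood pressure readings are mapped to the
sphygmomanometer scale with sex-specific affine adjustments
(SBP: 3.3171 + 0.92019·raw + 6.02468·male; DBP: 14.5647 + 0.80929·raw +
2.01089·male, mmHg). All downstream quantities, including mean BP
(SBP + 2·DBP)/3 and the hypertension threshold (≥140/≥90 mmHg), use the
adjusted scale. eGFR comes from the creatinine CKD-EPI equation (serum
creatinine in µmol/L divided by 88.4; κ = 0.7/0.9 and α = −0.329/−0.411
for women/men; 141 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.209 · 0.993^age ·
1.018 if female). Diagnostic flags are OR-compositions: hypertension
(BP, therapy, or diagnosis), diabetes (therapy, diagnosis, or glucose
≥ 7 mmol/L), dyslipidemia (TC ≥ 6.61, LDL ≥ 4.1, TG > 1.7 mmol/L, or
statins), CKD (eGFR < 60). Extreme ASI values outside mean ± 5 SD are
excluded in a single pre-split pass using the pre-filter mean and SD; the
rule is deliberately not iterated, and whether to apply it before or
after cohort splitting was an open choice — this pipeline applies it to
the full table first.

Cohort selection: the reference arm requires absence of all four
conditions and a complete record; the analysis arm requires hypertension
without a prior CV event, complete-case on every modelled variable
(classification trees cannot use rows with missing entries). "Prior CV
event" is a single boolean collapsing heart attack, angina and stroke;
chronic heart failure is not represented.

## Reference equation and stiffness index

The reference model is OLS of measured ASI on age, sex, mean BP and heart
rate with intercept, fitted via a numerically stable orthogonal/pseudo-
inverse decomposition (statsmodels) with the classical covariance
estimator. A rank-deficient design (e.g. a single-sex cohort) raises
rather than silently dropping a column. The stiffness index is
(measured − predicted)/predicted, requiring predicted ASI > 0; an index
of exactly 0 is classed negative because the positive class is defined
strictly by "> 0" and the two classes are exhaustive. The analysis cohort
is scored with the model fitted on the same run's reference cohort by
default; frozen (published) coefficients can be injected for replication
(`--frozen-coefficients` on the CLI).

Because OLS residuals are orthogonal to the fitted values, the mean
stiffness index over the fit cohort is zero up to the second-order term
of the ratio expansion; the acceptance suite verifies |mean| ≤ 0.005 at
n = 50,000.

## Classifier screening

Univariate screening uses the two-sided pooled-variance Student t for
continuous biomarkers and Pearson χ² without continuity correction for
categorical ones; candidates require p < 0.05; no multiple-testing
correction is applied (a property of the replicated procedure).
Zero-variance variables are reported with p = 1 and a warning.

Stepwise logistic selection: the procedure named in the source analysis
does not state its statistic, so entry and stay decisions both use the
likelihood-ratio test at α = 0.05: the forward step adds the candidate
with the smallest LR p-value if below α, the backward step removes any
included variable whose LR p-value is at or above α (largest first), and
steps alternate until stable; ties break alphabetically so runs are
deterministic. Logistic likelihoods are maximized by Newton/IRLS
(statsmodels) with convergence at a log-likelihood change below 1e-8 or
100 iterations; complete separation is detected, the fit is replaced by a
tiny-ridge (1e-6) stabilized optimum, flagged, and excluded from
selection.

ROC curves enumerate all distinct score thresholds; the AUC is the
trapezoid integral, which with ½-credit for ties equals the rank-sum
(Mann–Whitney) formulation exactly — both are implemented and the
identity is a property test. Youden cutpoints: orientation is fixed first
(direction "≥" when the oriented AUC favours higher scores, else "≤", so
AUC ≥ 0.5 after orientation), candidate cutpoints are midpoints between
consecutive distinct observed values (direction-symmetric, unlike
observed-value candidates), J is maximized over candidates, and J-ties
resolve to the smallest cutpoint with a 1e-12 tolerance guarding float
noise. Per-classifier thresholds and AUCs are computed on the raw
variable as the score, the convention that yields one threshold per
biomarker; the report ranks classifiers by sensitivity at the chosen
cutpoint (the "most sensitive … most specific" ordering is otherwise
unspecified and this interpretation is flagged here).

## Decision tree

Features are exclusively the Youden-binarized classifiers, with inclusive
comparators at the cutpoint (≥ / ≤ on the positive branch, strict
complements on the other). Growth: recursive binary splitting maximizing
the weighted Gini decrease (Gini = 1 − Σp²), stopping at purity, at
max_depth (default: the number of features), or when no admissible split
leaves both children with at least `min_leaf` = 20 rows. Zero-gain splits
are permitted when the node is impure: with binary features, balanced
interaction structure (XOR) has exactly zero marginal gain at the root,
and forbidding such splits would make interaction discovery — the point
of using a tree — impossible; spurious zero-gain growth is instead
removed by pruning. Split ties break alphabetically; no variable repeats
on a path.

Pruning is standard weakest-link cost-complexity: the penalty sequence is
computed bottom-up, candidate penalties are the geometric means of
consecutive sequence values plus 0 and ∞, and each candidate is scored by
stratified 10-fold cross-validated misclassification of trees grown on
the training folds and pruned at that penalty. The selected penalty is
the largest within one binomial standard error of the minimum (the 1-SE
rule). The plain minimizer was rejected because it retains chance
structure on noise labels in a majority of runs; the 1-SE rule is the
established remedy. A residual caveat is inherent to any such rule:
chance feature–label association in a fixed dataset is shared by all CV
folds, so with several noise features a small fraction of datasets
genuinely cross-validate better with a split than without.

Repeated cross-validation ("one hundred models") is interpreted as 100
stratified Monte-Carlo 80/20 train/test splits (configurable): each split
grows and prunes a tree on the training part and scores the held-out part
by the training positive-proportion of its leaf, giving a per-split AUC
and their mean. Rule extraction reports one candidate rule per leaf,
conditions root-first, and retains those with leaf n ≥ 20 and positive
rate strictly above 0.70; each rule also reports its first-step subgroup
size and rate.

## Evaluation

The DeLong test compares two AUCs on the same participants via
placement values computed with midranks; the variance of the paired
difference uses the empirical covariance of placement values across the
two scoring rules, and the two-sided p-value is normal with no continuity
correction. Equal estimated AUCs report z = 0, p = 1 even in the
degenerate zero-variance case (identical or rank-identical scores);
unequal AUCs with zero variance are flagged with an undefined p. Tree
scores for the comparison are leaf positive-proportions; logistic scores
are fitted probabilities; the pipeline's comparison is in-sample on the
full analysis cohort, with a repeated-CV tree AUC available as an option.
The collinearity report is the pairwise Pearson correlation matrix over
complete cases, with zero-variance columns reported as missing.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
calibrated to the published population moments, and is the package's test
bed; it is not a model of any real participant.

* **Healthy arm** (defaults: mean age 53.7 y, 40.5% male, adjusted SBP/DBP
  121.8/77.9 mmHg, HR 66.9 bpm): covariates are drawn independently per
  variable; measured ASI is the reference equation (−1.167, 0.0837/y,
  0.9337 male, 0.0402/mmHg, 0.0203/bpm) plus Normal(0, 2.6 m/s) noise —
  2.6 m/s makes the marginal ASI SD ≈ 2.76 m/s as reported, and implies
  R² ≈ 0.10 for the reference fit. Eligibility (SBP < 140, DBP < 90,
  glucose < 7 mmol/L, no therapy, no CV event, eGFR ≥ 60) is enforced by
  rejection sampling with an attempt cap of 100·n.
* **Hypertensive arm** (mean age 58.9 y, 60.4% male, SBP/DBP 145.7/87.1):
  all rows carry the doctor-diagnosis flag (therapy at the reported
  40.8%), which satisfies the hypertension definition without truncating
  the configured BP moments. A latent positive/negative stiffness class is
  drawn from a logistic model on the biomarkers whose slopes are the
  reported per-unit log-odds (e.g. phosphate +0.72 per mmol/L, HDL −0.31
  per mmol/L) and whose intercept (0.4265) was calibrated once so the
  expected positive fraction equals the reported 45.4% class split. The
  stiffness index is then drawn from class-conditional truncated normals
  (positive: mean 0.2552, SD 0.2231, truncated to > 0; negative: −0.2410,
  0.1573, < 0) and measured ASI reconstructed as predicted·(1 + index),
  so the index sign always matches the latent class.
* **Distribution families.** Most variables are truncated normals whose
  parent parameters are solved numerically so the *truncated*
  distribution matches the configured mean/SD (plain truncation would
  shift, e.g., healthy SBP by ~1 mmHg). Triglycerides are moment-matched
  log-normal and pack-years zero-inflated exponential (≈63–67%
  never-smokers), respecting their skew; testosterone is a two-component
  normal by sex with a fixed female component (1.1 ± 0.6 nmol/L) and the
  male component solved to preserve the pooled moments.
* **Randomness.** Every draw flows from the single config seed through
  named substreams, one per (arm, variable), so adding or removing a
  variable does not perturb the others and identical config + seed gives
  a bit-identical table. The generator emits raw device-scale BP by
  inverting the adjustment formulas, so preprocessing performs real work.
* **Interaction demonstration.** `interaction_demo_config()` adds two
  strong pairwise terms to the class logit on standardized scales
  (HDL × pack-years −1.5; phosphate × urate +1.5) — non-additive
  structure a main-effects logistic model cannot represent. Under these
  conditions the tree's in-sample AUC exceeds the logistic AUC and rules
  clearing the 70%/20 filters appear, with purities (≈72–86%) resembling
  the reported rule profile. Note that a strong interaction can reverse a
  biomarker's *marginal* association (HDL's does), so
  direction-vs-coefficient-sign checks use the main-effects conditions.

**What the generator does not emulate:** biomarker–biomarker correlations
(draws are independent per variable; the real collinearity structure is
only partially published), SBP–DBP correlation (the derived mean-BP SD is
~5.4 vs the reported 6.99 mmHg; its mean matches), longitudinal
structure, medication effects on biomarkers, and measurement error in
ASI beyond additive Gaussian noise. Consequently, passing tests establish
that the *procedures* are implemented correctly and recover known
structure, not that the published real-data thresholds, rule percentages
or AUCs (which depend on the access-controlled survey data) are
reproduced. Two reported figures are intentionally not matched: the
healthy-arm creatinine/testosterone/age moments shift slightly because
the eGFR eligibility filter removes a high-creatinine (mostly female)
tail — the calibration tests compare against an eligibility-aware
oracle — and the hypertensive mean stiffness index is ≈ −0.016 rather
than the reported +0.0163, because the reported class-conditional index
moments and class split jointly imply the negative value.

## Problem sizes and runtime choices

Coefficient-recovery and calibration checks run at n = 50,000 per arm
(seconds). The end-to-end tree demonstration runs at 20,000 hypertensive
participants with the in-sample DeLong comparison; repeated-CV property
tests use reduced sizes and split counts (e.g. n ≤ 1,000, 10–20 splits),
which estimate the same quantities at proportionally larger Monte-Carlo
error. The pure-noise pruning property is asserted at n = 1,000, four
binary features, prevalence 0.40 and min_leaf 20 over 50 seeded runs.
Default pipeline constants (0.05 entry/stay, 0.70 rate floor, 20 minimum
leaf, 5-SD outlier band, 100 CV splits) live in configuration objects,
never in stage logic.

## Known limitations

* The stepwise procedure's statistic, the cross-validation scheme behind
  "one hundred models", and the Youden candidate-cutpoint convention are
  under-determined in the source description; the choices above are
  documented interpretations, deterministic and configurable.
* Greedy CART is not an optimal-tree algorithm: on adversarial instances
  (an informative distractor masking an interaction) it is provably
  suboptimal at fixed depth; tests bound it between the exhaustive
  depth-2 optimum and the best single split and check ≥95% prediction
  agreement with an independent reference implementation.
* The DeLong p-value is a large-sample normal approximation; at n = 20 it
  agrees with a 100,000-replicate stratified paired bootstrap to within
  0.02 away from the AUC-tie region, where percentile p-values are
  intrinsically unstable.
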