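# Methods

This note documents the models and procedures implemented in `myoscreen`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate about real screening data.

## 1. The screening rules

### Refractive classification

The classifier over spherical equivalent (SE, diopters) is an ordered
IF/ELSE chain (see the README for the clause list). Two details deserve
explanation:

**Boundary semantics.** Cut points follow the comparison operators of the
underlying guideline logic verbatim: SE = +0.75 and SE = −0.50 are
pre-myopic, SE = −3.00 is low myopia, SE = −6.00 is moderate myopia, and
AL/CR exactly 3.00 fires the risk flag. In non-cycloplegic mode, myopia
is SE ≤ −0.75, so SE = −0.75 itself is myopic. The two modes provably
differ only on the open band −0.75 < SE < −0.50 (tested by grid scan).

**Borderline high hyperopia.** A child with SE above +0.75 D but still
inside the age's hyperopia-reserve interval is grouped with pre-myopia,
as the guideline chain dictates, but fires a distinct trace identifier
(`premyopia_borderline_high_hyperopia`) so the subgroup remains
recoverable for audit.

Visual acuity is deliberately supplementary: acuity worse than decimal
0.7 (logMAR > −log₁₀ 0.7 ≈ 0.155) for ages 6–12 sets a flag and a trace
entry but never overrides the SE-based category — no guideline provides
an override rule, and inventing one would not be auditable. Corneal power
K is accepted as an alternative input and converted to radius via the
keratometric constant CR = 337.5 / K (configurable); conversion happens
only when K is supplied.

The percentage deviations of AL and CR from the age-matched reference
means are computed and exposed as features, but feed no rule decision:
no quantitative decision rule is defined for them, so they inform the
learners rather than the deterministic chain.

### Reference tables

The three age-indexed tables (hyperopia reserve, axial length, corneal
radius; ages 6–12, 21 rows) are shipped as CSVs inside the package so a
guideline revision is a one-file edit, and are validated on load
(interval ordering; strictly increasing axial maxima). The corneal table's
age-6 row differs markedly from ages 7–12; it is preserved verbatim, with
no smoothing. Lookups floor fractional ages to the completed year
(matching how "6/0"-style ages are parsed); nearest-year rounding is a
constructor option. Requests outside 6–12 raise rather than extrapolate —
sources disagree on coverage above age 12, so the package refuses to
guess.

## 2. Preprocessing

All statistics that could leak information — imputation medians and
z-score parameters — are fitted on the training partition only and
applied frozen elsewhere; the test suite verifies that mutating the test
partition leaves fitted parameters bit-identical.

* **Imputation**: median within the (age, sex) stratum, falling back to
  the age stratum, then the global median. A feature with no observed
  value at all is an error, named.
* **Scaling**: per-feature z-scores. Zero-variance features are recorded
  at fit time and transformed to zeros with a warning, never divided.
* **Plausibility**: the only published screening threshold is AL > 30 mm;
  the remaining defaults (AL ∈ [18, 30] mm, CR ∈ [6.5, 9.5] mm,
  SE ∈ [−15, +10] D, acuity ∈ [−0.3, 1.5] logMAR, age ∈ [6, 12]) are
  package choices covering the physiological range of school-aged eyes,
  kept as visible, overridable configuration. Flagged rows are
  quarantined with named flags and an empty `reviewer_decision` column;
  human review is staged, not automated away — nothing re-enters without
  an explicit "keep".
* **Pseudonymization**: the identifying fields are pipe-joined in input
  order, UTF-8 encoded, SHA256-hashed; the id is the first 16 hex digits,
  uppercased, grouped 4-4-4-4. The grouped-16-character format is the
  contract; taking the digits from the hex digest (rather than some other
  alphabet) is this package's documented interpretation, chosen for
  determinism and verifiability.

## 3. The synthetic cohort generator

The generator emulates a hospital-clinic developmental cohort of 6–12
year olds: n = 1006, 49.7% boys, class mixture
(hyperopia, pre-myopia, low, moderate, high myopia) =
(10.74, 52.68, 31.01, 4.87, 0.70)%, mean SE ≈ −0.66 D, mean AL ≈ 23.56 mm,
mean AL/CR ≈ 3.05, mean acuity ≈ 0.68 logMAR.

Generation is **class-first**: the category is drawn from the mixture
(by default with exact largest-remainder allocation, so even the 0.7%
high-myopia class appears at small n; multinomial draws are an option),
then SE is drawn inside that category's rule interval, so the rule
engine reproduces the drawn class by construction under the generator's
mode (non-cycloplegic by default). Within-class SE distributions are
triangular; their modes are calibration constants chosen once so the
mixture-weighted mean SE lands near −0.66 D:

* hyperopia: uniform on (reserve_upper, reserve_upper + 1.0] D,
* pre-myopia: triangular(−0.75, mode −0.30, +0.75),
* low myopia: triangular(−3.0, mode −3.0, −0.75),
* moderate: triangular(−6.0, mode −4.0, −3.0),
* high: triangular(−9.0, mode −6.5, −6.0).

Biometry follows the axial-coupling model

    CR ~ Normal(cr_ref_mean(age) − 0.23, 0.18) clipped to the age interval
    AL = CR · 3.021 − SE / 3 + Normal(0, 0.3)

i.e. an emmetropic eye sits at AL/CR = 3.021 and each diopter of myopic
shift adds 1/3 mm of axial length (the ~3.00 D-per-mm axial relation);
this makes AL/CR strongly negatively correlated with SE (empirically
r ≈ −0.91). Two calibration facts deserve honesty:

* The target cohort's mean AL (23.56 mm) and mean AL/CR (3.05) jointly
  imply a mean CR near 7.72 mm, which sits ~0.23 mm below the
  population reference means. That is plausible for a myopia-clinic
  cohort (steeper corneas than the general population) and is encoded as
  the `cr_mean_shift` default; every age's shifted mean remains inside
  its published reference interval. Anchoring AL at the population
  age-mean axial lengths instead cannot reproduce both targets at once.
* The target summary's training-column AL/CR spread (0.84) is an order
  of magnitude larger than its tuning/test columns (0.14/0.12) and is
  treated as a misprint; the generator produces a spread of ≈ 0.10,
  consistent with the latter. Likewise the generated AL spread
  (≈ 0.95 mm) is narrower than the reported 1.53 mm; the means, not the
  spreads, are the calibration contract.

Acuity is logMAR = 0.42 + 0.25·max(−SE, 0) + Normal(0, 0.25), clipped to
[−0.1, 1.5] — a package-chosen functional form whose parameters reproduce
the target mean empirically. Ages are uniform over 6–12. Sphere and
cylinder are decomposed from SE (half-normal cylinder, scale 0.3 D).
Missingness is MCAR by default over acuity/AL/CR (an age-dependent MAR
option exists for imputation stress tests); outliers replace AL with
implausible values above 30 mm. Both rates default to zero: the emulated
summary describes complete, reviewed records.

**What passing tests do not show about real data.** Real SE is quantized
to 0.25 D steps, eyes come in correlated pairs, refraction and biometry
carry device- and operator-level error structure, and the true
class-conditional SE distributions are not triangular. The generator
demonstrates that the pipeline's mechanics (stratification, imputation,
rule-feature learning, evaluation) are correct, not that any accuracy
measured on synthetic data transfers to a clinical population. The
cohort is also per-child, not per-eye.

## 4. The model harness

* **Split**: 70/15/15 stratified by class, allocated class-by-class with
  largest-remainder rounding — deterministic under the split seed,
  disjoint and exhaustive; classes with fewer than 3 members produce a
  warning and best-effort allocation.
* **Features** (15): eight z-scored continuous features (age, acuity, SE,
  AL, CR, AL/CR, AL and CR percent deviation from age reference means),
  the sex code, and the six rule features — a one-hot of the five
  categories plus the risk flag, each multiplied by `rule_feature_weight`
  (default 1.0). Categorical blocks are deliberately not z-scored, so a
  weight of w means "w standard-deviation units of evidence".
* **Bench**: gradient boosting, logistic regression, random forest, SVM
  (RBF, one-vs-rest decision values), XGBoost, all with mainstream
  library defaults recorded in the run log; the random forest carries an
  explicit `max_depth=10` so the self-healing "deepen the trees" action
  is well defined. Class imbalance is handled by stratification only
  (optional class weighting is available via hyperparameters), and
  wall-clock fit time is logged but is explicitly not a performance
  claim — it is hardware-dependent.
* **Refinement loop**: up to `max_refinement_cycles` cycles (default 50;
  configurable to arbitrarily large budgets) monitor validation accuracy
  and log it per cycle. A relative drop of more than 20% versus the best
  accuracy observed so far triggers the per-algorithm corrective action —
  random forest: trees ×2 and depth +2; gradient boosting and XGBoost:
  learning rate ×0.5; logistic regression: iteration cap ×2; SVM: C ×2 —
  followed by a refit. The trigger is defined relative-to-best because
  absolute 20-point drops essentially never occur at high accuracy.
  Estimators are refitted only when an action changed their
  hyperparameters: refitting an unchanged deterministic estimator every
  cycle would be pure waste, so ordinary cycles are monitoring steps.
  With deterministic monitoring on a fixed validation set the series is
  constant and the trigger provably never fires (tested); the
  `resample_validation` option bootstraps the validation set each cycle,
  which makes the monitored series stochastic and exercises the trigger
  end-to-end.

**The rule-enhancement mechanism, falsifiably.** On noiseless
rule-labeled data the label is a deterministic function of the one-hot
rule block, so any tree model with a positive rule weight must reach
near-perfect test accuracy — observed ≥ 0.99 for random forest, XGBoost
and gradient boosting at n = 1436 — and a paired-seed ablation (weight 1
vs weight 0, ten seeds) must show no accuracy loss from including the
rule block. These two tests are what "the rules guide the learners"
means operationally.

## 5. Evaluation

Accuracy, support-weighted precision/recall/F1 and per-class accuracy
(the confusion-matrix diagonal over row sums) follow standard multiclass
definitions; the confusion matrix is row-true/column-predicted in the
clinical class order. One-vs-rest AUC uses the tie-aware rank
(Mann–Whitney) statistic, verified against brute-force pairwise
concordance to 1e−12; the mean AUC is unweighted over classes with at
least one positive and one negative (a support-weighted variant is a
flag). Classifier scores are predicted probabilities where available and
one-vs-rest decision-function values otherwise (SVM).

Three interval procedures, each tagged on the result:

* **Percentile bootstrap** (default B = 1000, seeded, bit-reproducible):
  resamples cases; a resample on which the metric is undefined (e.g. a
  single-class draw) is redrawn and counted.
* **Wilson score** for proportion metrics; endpoints at p = 0 and p = 1
  are set to their exact algebraic values (0 and 1) to avoid floating-point
  residue.
* **Hanley–McNeil** for AUC, with Q1 = A/(2−A), Q2 = 2A²/(1+A), clipped
  to [0, 1].

Learning curves refit the estimator on growing stratified subsets and
report mean ± sd of train and held-out accuracy over folds (one fold
yields zero sd). Plots (ROC, confusion heatmap, learning curve) are
file artifacts; the numerical tables are the contract.

## 6. Problem sizes and defaults used in the shipped experiments

The test suite and the reproduction script use the cohort sizes the
emulated study reports (1006 for calibration, 1436 for the
rule-enhancement check) plus a 10,000-subject cohort for tight
calibration bounds; ablations use n = 600 over ten seeds, and bootstrap
checks use B = 1000. All randomness flows through explicit integer
seeds; the grid scans (boundary recovery, partition agreement) are
deterministic.

## 7. Known limitations

* Supported ages are exactly 6–12; no extrapolation of reference values.
* Cross-sectional only: the framework classifies current status and
  flags structural risk; it does not model progression over time.
* The synthetic generator's per-class SE shapes, acuity model and
  missingness mechanisms are stylized (see §3); results on synthetic
  data validate mechanics, not clinical performance.
* No cycloplegic-branch variant beyond the reserve-upper hyperopia test:
  no separate dilated-mode decision chain is defined by the sources the
  rules encode.
* The self-healing loop's corrective actions are fixed multiplicative
  steps; it is a robustness mechanism, not a hyperparameter search.
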