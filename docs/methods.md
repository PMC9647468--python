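# Methods

This note documents the models and procedures implemented in `nutriscreen`,
the parameter defaults and why they were chosen, what the synthetic-cohort
generator does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## Screening instruments

### NRS-2002 (final screening only)

The engine implements the final-screening worksheet: three components that
sum to a 0–7 total, with risk flagged at total ≥ 3.

* **Impaired nutritional status (0–3)** is the *worst* of three subscores
  ("worst category" rule):
  * weight loss — 5–15% of body weight over 3/2/1 months scores 1/2/3;
    loss exceeding 15% scores 3 at any timeframe (the worksheet's
    "≈15% in 3 months" rule, applied conservatively to shorter windows);
  * BMI — below 18.5 kg/m² scores 3, 18.5–20.5 scores 2, otherwise 0.
    The worksheet attaches an "impaired general condition" qualifier to
    the BMI criterion; the questionnaire collects no such item, so it is
    treated as satisfied — a reasonable assumption for hospitalized
    oncology inpatients, the engine's intended population;
  * intake reduction — bins of roughly 25–50%, 50–75% and 75–100% of
    usual intake score 1/2/3 (these mirror the worksheet's "50–75% /
    25–50% / 0–25% of requirement remaining" bins).
* **Disease severity (0–3)** is the worst selected entry of an editable
  disease catalogue. The shipped catalogue seeds the worksheet's prototype
  categories (solid tumor 1, hematologic malignancy and major abdominal
  surgery 2, intensive-care-level illness 3, plus zero-severity chronic
  conditions); deployments are expected to extend it.
* **Age (0–1)**: one point at or above 70 years (threshold configurable).

The initial pre-screening stage of the published instrument is
deliberately not implemented: in the deployment pattern this engine
mirrors, only the final screening is administered.

### Reduced PG-SGA short form

Three patient-completed boxes — weight history, food intake, symptoms —
with risk flagged at total ≥ 4. The activities-and-function box of the
full short form is intentionally excluded. The published worksheet's exact
point values for this reduced, app-adapted variant are not standardized,
so the mapping ships as configuration with defaults chosen to preserve the
worksheet's ordering:

* weight history: stable/gain 0, 5–15% loss 3, >15% loss 4, plus 1 point
  when the loss occurred within one month;
* food intake: the worst ("greatest box score") of intake reduction
  (0/1/2/3) and diet texture (normal 0, soft 1, liquid 2, fasting 4);
* appetite symptoms: never 0, occasionally 1, frequently 3.

Only the monotone ordering and the cutoff are load-bearing anywhere in the
package; no analysis depends on the specific point values, and the test
suite checks monotonicity, boundedness and cutoff consistency over the
entire finite response space.

### Display conventions and degenerate inputs

BMI and the kilogram equivalents of 5%/15% weight loss are displayed to
one decimal; scoring always uses full precision. Note that percentage-
based thresholds are the rule implemented here: for a 58 kg patient the
options render as 2.9 and 8.7 kg. (Some published descriptions of
comparable apps print inconsistent kilogram examples for this calculation;
the percentage rule is the defensible one.) Ages outside 18–80 and BMI
outside (10, 60) kg/m² are scored but raise a `ClinicalRangeWarning` —
the engine never silently refuses plausible clinical data; structurally
invalid input (non-positive height/weight, missing loss timeframe,
unknown disease codes) raises `ValidationError`.

## Dietary assessment

The 3-item estimator is linear in the reported daily amounts of rice (g),
meat (g) and milk (mL):

    energy  = b0_E + Σ_i a_i · (amount_i / 100) · energy_density_i
    protein = b0_P + Σ_i a_i · (amount_i / 100) · protein_density_i

The shipped table uses cooked-food densities (rice 116 kcal & 2.6 g,
mixed meat 250 kcal & 20 g per 100 g; whole milk 65 kcal & 3.0 g per
100 mL), zero intercepts, and a multiplicative adjustment of 1.25 per item
that stands in for energy and protein from foods the 3-item recall does
not ask about (cooking oil, vegetables, eggs). These are package defaults
for a generic hospital setting — *not* coefficients fitted to any survey —
and live entirely in configuration; any deployment that has pilot recall
data should calibrate its own table and bump the version string, which is
carried into every estimate. "Meat" pools red meat, poultry and fish under
one density; amounts are as-consumed weights with no raw-to-cook
conversion (that belongs to reference-method workflows, out of scope
here). Item amounts above 2000 g (or mL) per day warn as implausible.

Requirements are weight-proportional with defaults of 25 kcal/kg/day and
1.2 g protein/kg/day — mid-range of standard guidance for hospitalized
adult patients — overridable per call. The gap is intake − requirement,
so deficits are negative.

## Validation statistics

* **Proportion CIs** default to Clopper–Pearson (exact); Wilson is
  available by flag. Point estimates, not CI variants, are the quantities
  the package treats as primary.
* **Cohen's κ** uses the large-sample (Fleiss-Cohen-Everitt) standard
  error for its CI, cross-checked in the test suite against statsmodels.
  Degenerate margins (expected agreement 1) are flagged, not NaN.
* **McNemar's test** defaults to the χ² form without continuity
  correction (flag to enable) and switches to the exact two-sided
  binomial automatically below 25 discordant pairs. The no-discordance
  table returns statistic 0, p = 1.
* **Correlation**: `auto` picks Pearson when both margins pass a
  Lilliefors (Kolmogorov–Smirnov-type) normality screen at α = 0.05, else
  Spearman; fewer than four observations cannot support normality and
  fall back to Spearman. CIs use the Fisher z-transform with
  SE = 1/√(n−3) (tagged, and approximate for Spearman).
* **Paired agreement**: differences are app − reference; relative
  differences use the per-pair reference as denominator, excluding (and
  counting) pairs with non-positive reference. The location test is a
  paired t-test when the differences pass the normality screen, otherwise
  the Wilcoxon signed-rank test; an all-zero difference vector is
  reported as degenerate with p = 1.
* **Validity grading** (reported per criterion, never merged):
  sensitivity and specificity both above 80% = good, either below 50% =
  poor, otherwise fair; correlation bands at 0.75 and 0.4; κ bands at 0.6
  and 0.4. Undefined inputs grade "undetermined".

Every statistic that can be undefined carries an explicit `defined` flag
and note; nothing is reported as silent NaN.

## Synthetic-cohort simulator

The generator emulates the structure a paired validation study of a
self-administered screening app assumes. Defaults describe a 244-patient
hospital oncology cohort: reference-positive prevalence 17.2% with index
sensitivity 81.0% and specificity 76.7% in the NRS-2002 arm (23.8% /
84.5% / 64.5% in the PG-SGA-SF arm); age log-normal matched to median 59
(IQR 51–68) years truncated to 18–80; weight normal (58.6, SD 8.9) kg
truncated above 30 kg; BMI normal (22.2, SD 2.9) truncated to (13, 45);
height derived from weight and BMI so the triplet is consistent; 63.9%
male.

Questionnaire answers are sampled **uniformly from the satisfying set**:
the finite response space is enumerated through the scoring engine itself
and a combination is drawn among those that map to the record's index
flag, so scoring every synthetic record reproduces its flag by
construction. Any non-uniform weighting over the satisfying set would be
unidentifiable from aggregate validation tables, so uniform is the
declared choice. For the NRS arm, anthropometrics whose BMI/age subscores
alone already reach the cutoff are redrawn when the record must be
index-negative (they make a negative flag unsatisfiable).

Paired intakes use a structured Gaussian copula. Energy is bivariate
normal — reference N(1434.1, 528.8²), app N(1578.3, 468.4²), correlation
0.59 — which simultaneously reproduces a mean app−reference difference of
144.2 kcal and a difference SD of ≈455 kcal; an additive
reference-plus-noise model could not, since the app's SD is *smaller*
than the reference's. Protein margins are log-normal matched to medians
61.7/79.0 g and their IQRs, with copula correlation 0.47. A
within-person energy-protein correlation of 0.60 (typical of diet data)
completes the 4-variable dependence structure. Draws with non-positive
energy are rejected and redrawn, which shifts the asymptotic energy bias
by roughly −5 kcal — well inside the tolerances used anywhere.

The stored app energy/protein values are the drawn (exactly calibrated)
ones. The 3-item food amounts are back-solved from them (milk drawn
uniformly on 0–300 mL, rice and meat from the resulting 2×2 linear
system); when a drawn energy-to-protein ratio falls outside what
rice/meat/milk can jointly realize (about 5–9% of records, protein-heavy
tails), the amounts are projected onto the nearest representable diet, so
re-assessing the amounts reproduces the stored values only approximately
for those records.

**What passing tests do and do not show.** The simulator reproduces the
*marginal and pairwise* structure of a validation study — prevalence,
conditional flag probabilities, intake moments and correlations — under
non-differential misclassification (index errors independent of
demographics) and with the two instruments' arms simulated separately
(their within-patient joint distribution is not identified by marginal
tables). Recovery of the configured quantities by the pipeline therefore
validates the *statistical machinery*, not the instruments' real-world
accuracy; real cohorts have differential misclassification, correlated
instruments and reporting behaviour the generator does not model.

## Problem sizes and numerical choices

The test suite exercises large-sample calibration at n = 10⁵ records for
classification (tolerances ≈ 4 binomial SEs), n = 10⁴ for the intake
model (correlation within ±0.05), and the recovery experiment at the
study size n = 244 over 200 replicates — sizes chosen so the full suite
runs in well under a minute of simulation time while leaving Monte-Carlo
tolerances meaningful. Replicate seeds derive from the base seed via
NumPy's `SeedSequence`; identical config and seed give bit-identical
cohorts, reports and pipeline outputs (timestamps are deliberately kept
out of analytic outputs, and output paths are excluded from the run-config
hash). All scoring is integer arithmetic; rounding (percentages to one
decimal, κ and correlations to two) applies only at display and report
boundaries.

## Known limitations

* The shipped PG-SGA-SF point map and food-composition calibration are
  documented defaults, not fitted coefficients; deployments should supply
  their own configuration where fidelity to a specific instrument
  printing or survey matters.
* Requirement estimation is weight-proportional only (no stress/activity
  factors, no indirect calorimetry hooks).
* The simulator does not model dropout, item-level response
  distributions beyond flag consistency, or any within-patient link
  between the two instruments' flags.
* Spearman CIs reuse the Fisher-z form, a common approximation that is
  slightly anticonservative for strong correlations.
* No ROC/AUC analysis: the instruments are binarized at their published
  cutoffs, and the validation surface is the paired 2×2 design.
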