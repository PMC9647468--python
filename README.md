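# nutriscreen

Nutritional-risk screening, quick dietary assessment and diagnostic-accuracy
validation for hospitalized patients — the computational core of
self-administered smartphone screening tools, packaged as a Python library
with a CLI, plus the statistics needed to validate such a tool against
dietitian-administered reference methods and a calibrated cohort simulator.

**Who it is for.** Clinical-nutrition researchers and engineers who need
(1) reproducible, configurable implementations of the NRS-2002 final
screening and a reduced PG-SGA short form, (2) a 3-item (rice/meat/milk)
energy and protein intake estimator with guideline-based requirements, and
(3) the validation machinery of paired diagnostic-accuracy studies —
sensitivity/specificity/PPV/NPV with binomial CIs, Cohen's κ, McNemar's
test, correlation with automatic Pearson/Spearman selection,
paired-difference summaries and good/fair/poor validity grading.

## The instruments and statistics

**NRS-2002 (final screening).** Total = impaired nutritional status (0–3)
+ disease severity (0–3) + age (1 point at ≥70 y), with nutritional status
the worst of three subscores: weight loss (5–15% over 3/2/1 months → 1/2/3;
>15% → 3), BMI (<18.5 → 3; 18.5–20.5 → 2) and intake reduction
(25–50/50–75/75–100% → 1/2/3). Total ≥ 3 flags nutritional risk.

**Reduced PG-SGA short form.** Weight history + food intake (intake
reduction and diet texture, combined by the worst box entry) + appetite
symptoms; total ≥ 4 flags risk. Point maps ship as editable configuration.

**Dietary assessment.** Intake is linear in the three reported amounts:
`energy = b₀ + Σᵢ aᵢ·(amountᵢ/100)·energy_densityᵢ` (protein analogous),
against a versioned food-composition table; requirements are
weight-proportional (defaults 25 kcal/kg/day, 1.2 g protein/kg/day); the
reported gap is intake − requirement.

**Validation.** For a paired 2×2 table with cells (tp, fp, fn, tn):
sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp), NPV
tn/(tn+fn), accuracy (tp+tn)/n, κ = (p_o − p_e)/(1 − p_e), McNemar
χ² = (|fp − fn| − c)²/(fp + fn) with an exact binomial fallback for < 25
discordant pairs. Grading: sensitivity+specificity both > 80% = good,
either < 50% = poor, else fair; CC bands at 0.75/0.4; κ bands at 0.6/0.4.

## Worked example

```python
from nutriscreen import *

profile = PatientProfile("pt-001", age_years=72, sex=Sex.MALE,
                         height_cm=170.0, weight_kg=60.7)
print("BMI:", round(compute_bmi(profile), 1))
print("5%/15% loss thresholds (kg):", weight_loss_display_thresholds(profile))

nrs = score_nrs2002(
    profile,
    WeightChangeResponse(WeightChangeCategory.LOSS_5_TO_15PCT, timeframe_months=2),
    IntakeReductionResponse(IntakeReductionCategory.REDUCTION_50_75),
    DiseaseSelection(["solid_tumor"]),
)
print("NRS-2002:", nrs.components, "total", nrs.total, "at risk:", nrs.at_risk)

est = estimate_intake(IntakeReport(rice_g=300, meat_g=150, milk_ml=250))
req = estimate_requirements(profile)
gap = intake_gap(est, req)
print(f"intake {est.energy_kcal:.0f} kcal / {est.protein_g:.1f} g protein; "
      f"requirement {req.energy_kcal:.0f} kcal / {req.protein_g:.1f} g; "
      f"gap {gap.energy_kcal:+.0f} kcal / {gap.protein_g:+.1f} g")

table = ContingencyTable2x2(tp=34, fp=47, fn=8, tn=155)
report = diagnostic_report(table)
m = report.metrics
print("sens %.1f%%  spec %.1f%%  kappa %.2f  grade: %s" % (
    100*m["sensitivity"].value, 100*m["specificity"].value,
    report.kappa.value, report.grade_sens_spec))
print("McNemar p = %.2e" % report.mcnemar.p_value)
```

prints

```
BMI: 21.0
5%/15% loss thresholds (kg): (3.0, 9.1)
NRS-2002: {'nutritional_status': 2, 'disease_severity': 1, 'age': 1} total 4 at risk: True
intake 1107 kcal / 56.6 g protein; requirement 1518 kcal / 72.8 g; gap -411 kcal / -16.2 g
sens 81.0%  spec 76.7%  kappa 0.42  grade: fair
McNemar p = 1.45e-07
```

The patient scores 4 on the NRS-2002 (weight-loss subscore 2 over two
months, cancer = disease severity 1, one age point), so they are flagged
as at nutritional risk, and their reported diet leaves a 411 kcal/day
energy deficit against the guideline requirement. The 2×2 example is a
244-patient validation table: 81% of reference-positive patients are
caught by the index test, specificity is 76.7%, chance-corrected agreement
κ = 0.42 ("fair" band), and McNemar's test shows the index test flags
significantly more patients than the reference.

## Command line

```bash
nutriscreen simulate --instrument nrs2002 --n 244 --seed 7 --out cohort.csv
nutriscreen score    --in cohort.csv --out scores.csv
nutriscreen assess   --in cohort.csv --out assess.csv
nutriscreen validate --in cohort.csv --out report.json --instrument nrs2002
nutriscreen pipeline --in cohort.csv --out-dir run/
```

The five subcommands share one cohort CSV schema and compose into a
simulate → score → assess → validate pipeline. Exit codes: 0 success,
1 validation/configuration failure, 2 unexpected error.

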