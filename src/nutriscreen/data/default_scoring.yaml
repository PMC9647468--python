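# Default scoring configuration for the screening instruments.
#
# Point mappings follow the published NRS-2002 worksheet and the ordering of
# the published PG-SGA short-form boxes.  Everything here is configuration:
# deployments may override any mapping, but the shipped defaults are what the
# test suite and the documentation describe.
version: "scoring-default-1"

nrs2002:
  cutoff: 3
  age_threshold_years: 70
  # Impaired nutritional status = max(weight-loss, BMI, intake-reduction) points.
  weight_loss_points:
    stable_or_gain: 0
    loss_5_to_15pct: {3: 1, 2: 2, 1: 3}   # keyed by timeframe in months
    loss_over_15pct: {3: 3, 2: 3, 1: 3}
  bmi_points:
    severe_below: 18.5     # BMI < 18.5            -> 3 points
    moderate_below: 20.5   # 18.5 <= BMI < 20.5    -> 2 points, else 0
  intake_points:
    unchanged: 0
    reduction_25_50: 1
    reduction_50_75: 2
    reduction_75_100: 3

pgsgasf:
  cutoff: 4
  weight_points:
    stable_or_gain: 0
    loss_5_to_15pct: 3
    loss_over_15pct: 4
  one_month_bonus: 1       # extra point when the loss occurred within 1 month
  intake_points:
    unchanged: 0
    reduction_25_50: 1
    reduction_50_75: 2
    reduction_75_100: 3
  texture_points:
    normal: 0
    soft: 1
    liquid: 2
    fasting: 4
  appetite_points:
    never: 0
    occasionally: 1
    frequently: 3

# Disease catalogue: code -> NRS-2002 disease-severity points (0-3).
# Seeded with the NRS-2002 prototype categories; editable per deployment.
disease_catalogue:
  hypertension: 0
  chronic_disease_stable: 0
  solid_tumor: 1
  diabetes_mellitus: 1
  hip_fracture: 1
  copd_acute_exacerbation: 1
  cirrhosis_with_complications: 1
  chronic_hemodialysis: 1
  major_abdominal_surgery: 2
  hematologic_malignancy: 2
  stroke: 2
  severe_pneumonia: 2
  intensive_care_illness: 3
  bone_marrow_transplantation: 3
  severe_head_injury: 3
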