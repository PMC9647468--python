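# Default food-composition / calibration table for the 3-item dietary recall.
#
# Densities are per 100 g (rice, meat) or 100 mL (milk) of the food as
# consumed.  The multiplicative adjustment absorbs energy and protein from
# foods the 3-item recall does not ask about (cooking oil, vegetables, eggs).
# These are package defaults for a generic hospital setting, not coefficients
# fitted to any particular survey.
version: "composition-default-1"

intercept_energy_kcal: 0.0
intercept_protein_g: 0.0

items:
  rice:
    energy_kcal_per_100: 116.0
    protein_g_per_100: 2.6
    adjustment: 1.25
  meat:
    energy_kcal_per_100: 250.0
    protein_g_per_100: 20.0
    adjustment: 1.25
  milk:
    energy_kcal_per_100: 65.0
    protein_g_per_100: 3.0
    adjustment: 1.25
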