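# Enteral formula compositions, per 100 kcal (canonical route).
# Per-100-mL values follow from the caloric density (kcal per mL).
#
# high_protein_diabetes_new: new-generation diabetes-specific high-protein
#   formula (slow carbohydrates, MUFA, omega-3 EPA+DHA, high fiber).
# high_protein_standard: standard high-protein formula (higher carbohydrate,
#   1.4 kcal/mL, less fiber).
# high_protein_diabetes_control: widely used diabetes-specific high-protein
#   formula (MUFA-rich, fructose/maltitol carbohydrates).
formulas:
  high_protein_diabetes_new:
    caloric_density_kcal_per_ml: 1.0
    protein_g: 5.7
    carbohydrate_g: 8.2
    fat_g: 4.4
    fat_saturated_g: 1.1
    fat_mufa_g: 2.2
    fat_pufa_g: 1.0
    epa_dha_mg: 67.6
    fiber_g: 1.8
    fiber_soluble_g: 1.4
    fiber_insoluble_g: 0.4
  high_protein_standard:
    caloric_density_kcal_per_ml: 1.4
    protein_g: 5.0
    carbohydrate_g: 10.93
    fat_g: 3.79
    fat_saturated_g: 1.0
    fat_mufa_g: 1.43
    fat_pufa_g: 1.37
    epa_dha_mg: 0.0
    fiber_g: 1.07
    fiber_soluble_g: 0.5
    fiber_insoluble_g: 0.57
  high_protein_diabetes_control:
    caloric_density_kcal_per_ml: 1.0
    protein_g: 5.0
    carbohydrate_g: 7.46
    fat_g: 5.44
    fat_saturated_g: 0.45
    fat_mufa_g: 3.58
    fat_pufa_g: 1.14
    epa_dha_mg: 0.0
    fiber_g: 1.44
    fiber_soluble_g: 0.21
    fiber_insoluble_g: 1.23
# Which formula each randomization arm receives.
arm_formulas:
  A: high_protein_diabetes_new
  B: high_protein_standard
  C: high_protein_diabetes_control
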