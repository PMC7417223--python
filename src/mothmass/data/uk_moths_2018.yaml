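# Published reference parameters for predicting moth dry body mass (mg) from
# forewing length (mm) on the natural-log scale:
#   ln(mass) = (reference_intercept + intercept_adj) + (reference_slope + slope_adj) * ln(length)
# Fitted to 600 individual moths (94 species, 11 families) light-trapped in
# northern England in 2018; four speciose families carry refined parameters,
# every other family uses the reference ("other") values.
reference_slope: 3.056
reference_intercept: -5.016
family_adjustments:
  Crambidae: {slope: -0.904, intercept: 1.361}
  Erebidae: {slope: -0.601, intercept: 1.294}
  Geometridae: {slope: -0.492, intercept: 0.344}
  Noctuidae: {slope: -1.297, intercept: 3.788}
grouping:
  threshold: 5
  other_label: other
  mapping:
    Crambidae: Crambidae
    Erebidae: Erebidae
    Geometridae: Geometridae
    Noctuidae: Noctuidae
provenance:
  source: published UK light-trap study, 2018 field season
  n_individuals: 600
  n_species: 94
  n_families: 11
  response: ln dry mass (mg)
  predictor: ln forewing length (mm)
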