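# Sensitivity to the admission-proportion (mix-share) bounds.
# Scenario labels follow the published grid, which skips "4"; scenario 3 is
# the benchmark.
variant: model_I
scenarios:
  - label: "1"
    overrides: {patient_types.I.mix_upper: 0.9}
  - label: "2"
    overrides: {patient_types.I.mix_upper: 0.8}
  - label: "3"
    overrides: {}
  - label: "5"
    overrides: {patient_types.I.mix_lower: 0.6}
  - label: "6"
    overrides: {patient_types.I.mix_lower: 0.4}
  - label: "7"
    overrides: {patient_types.II.mix_upper: 0.4}
  - label: "8"
    overrides: {patient_types.II.mix_upper: 0.3}
  - label: "9"
    overrides: {patient_types.III.mix_upper: 0.2}
  - label: "10"
    overrides: {patient_types.II.mix_upper: 0.3, patient_types.III.mix_lower: 0.05}
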