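# Full model under three mix-bound settings vs the relaxed variant without
# proportion constraints.
variant: model_I
scenarios:
  - label: "model_I/scenario 1"
    overrides: {patient_types.I.mix_upper: 0.9}
  - label: "model_I/scenario 2"
    overrides: {patient_types.II.mix_upper: 0.3}
  - label: "model_I/scenario 3"
    overrides: {patient_types.II.mix_upper: 0.3, patient_types.III.mix_lower: 0.05}
  - label: "model_II"
    variant: model_II
    overrides: {}
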