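# Sensitivity of the optimum to per-patient-day nursing hours.
# Scenarios 1-3 vary type I, 4-6 type II, 7-9 type III; 2, 5 and 8 are the
# unmodified benchmark.
variant: model_I
scenarios:
  - label: "1"
    overrides: {patient_types.I.nursing_hours: 1.75}
  - label: "2"
    overrides: {}
  - label: "3"
    overrides: {patient_types.I.nursing_hours: 1.25}
  - label: "4"
    overrides: {patient_types.II.nursing_hours: 1.25}
  - label: "5"
    overrides: {}
  - label: "6"
    overrides: {patient_types.II.nursing_hours: 0.75}
  - label: "7"
    overrides: {patient_types.III.nursing_hours: 0.75}
  - label: "8"
    overrides: {}
  - label: "9"
    overrides: {patient_types.III.nursing_hours: 0.25}
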