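# Reference instance: respiratory department, 28-day planning cycle.
# Capacities are the elective share (70%) of departmental totals; the other
# 30% is reserved for emergency admissions.  Targets are ~90% of available.
# The admission cap (28 days x 203 beds) and priority floor 0 are
# deliberately non-binding defaults.
horizon: 28
admission_cap: 5684
priority_floor: 0.0
patient_types:
  - id: I
    revenue: 170
    exam_hours: 1.5
    nursing_hours: 1.5
    priority_score: 9
    mix_lower: 0.5
    mix_upper: 0.7
  - id: II
    revenue: 160
    exam_hours: 1
    nursing_hours: 1
    priority_score: 6.5
    mix_lower: 0.1
    mix_upper: 0.2
  - id: III
    revenue: 150
    exam_hours: 1.5
    nursing_hours: 0.5
    priority_score: 3
    mix_lower: 0
    mix_upper: 0.1
resources:
  - id: bed
    available: 203
    target: 183
    cost_pos: 20
    cost_neg: 30
  - id: exam
    available: 201.6
    target: 181
    cost_pos: 20
    cost_neg: 30
  - id: nursing
    available: 561
    target: 512
    cost_pos: 20
    cost_neg: 30
survival_csv: los_survival.csv
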