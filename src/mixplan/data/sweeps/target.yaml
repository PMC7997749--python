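# Sensitivity to the target-capacity (goal utilization) level.
# Each scenario fixes the bed target and scales every resource's target to
# the same utilization fraction of its available capacity
# (183/203 ~ 90% up to 195/203 ~ 96%).  Scenario 1 is the benchmark.
variant: model_I
scenarios:
  - label: "1"
    overrides: {uniform_target_level: 183}
  - label: "2"
    overrides: {uniform_target_level: 185}
  - label: "3"
    overrides: {uniform_target_level: 187}
  - label: "4"
    overrides: {uniform_target_level: 189}
  - label: "5"
    overrides: {uniform_target_level: 191}
  - label: "6"
    overrides: {uniform_target_level: 193}
  - label: "7"
    overrides: {uniform_target_level: 195}
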