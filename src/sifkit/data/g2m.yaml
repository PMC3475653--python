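family: g2m
species:
- CycB
- MPF
- Wee1
- Cdc25
params:
  k_S: 0.2
  k_d: 0.008
  k25p: 0.008
  k25pp: 0.89
  kweep: 0.03
  kweepp: 0.18
  k_awee: 0.61
  k_iwee: 0.71
  k_a25: 0.8
  k_i25: 0.35
  J_awee: 0.9
  J_iwee: 0.21
  J_a25: 0.19
  J_i25: 0.93
initial_conditions:
  CycB: 0.01
  MPF: 0.01
  Wee1: 1.0
  Cdc25: 0.01
horizon: 50.0
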