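family: mapk_reduced
species:
- ShcGS
- RasGDP
- RasGTP
- Raf
- Raf*
- Mek
- Mek*
- Erk
- Erk*
params:
  c1: 69.0
  c2: 0.00077
  c3: 14.0
  c4: 50.0
  c5: 0.78
  c6: 8.3
  c7: 90000.0
  c8: 400000.0
  c9: 600000.0
  c10: 15.0
  c11: 1530.0
  c12: 4.0e-06
initial_conditions:
  ShcGS: 20000.0
  RasGDP: 20000.0
  RasGTP: 0.0
  Raf: 10000.0
  Raf*: 0.0
  Mek: 360000.0
  Mek*: 0.0
  Erk: 750000.0
  Erk*: 0.0
horizon: 100.0
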