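# Template for a MAPK model variant with alternative initial
# concentrations and/or rate constants (for example, sets calibrated to
# live-cell FRET measurements). Fill in every value; empty entries fail
# validation on load. Units: molecules/cell and minutes.
family: mapk_reduced
species: [ShcGS, RasGDP, RasGTP, Raf, "Raf*", Mek, "Mek*", Erk, "Erk*"]
params:
  c1:
  c2:
  c3:
  c4:
  c5:
  c6:
  c7:
  c8:
  c9:
  c10:
  c11:
  c12:
initial_conditions:
  ShcGS:
  RasGDP:
  RasGTP:
  Raf:
  "Raf*":
  Mek:
  "Mek*":
  Erk:
  "Erk*":
horizon: 100.0
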