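# Calibrated reference surrogate wound-healing model.
# Produced by scarscreen.calibration.calibrate_defaults (seeded search);
# verified against constraints C1-C5 by the test suite.
name: reference-surrogate
parameters:
  kP: 0.35
  rI: 1.0
  rI8: 0.8
  K8: 0.3
  KI10: 0.3
  dI: 0.4
  rM: 0.3
  dM: 0.2
  rF: 0.08
  KT: 1.5
  gF: 0.2
  Fmax: 20.0
  aF: 0.25
  pTP: 0.1
  pTM: 0.7
  pTF: 0.015
  dT: 0.3
  p6: 0.8
  d6: 0.5
  p8P: 0.5
  p8I: 0.3
  d8: 0.8
  p10: 0.6
  d10: 0.04
  p9: 0.8
  d9: 0.3
  pT1M: 0.3
  pT1F: 0.15
  e10: 4.0
  K10e: 0.3
  dT1: 0.25
  pFN: 0.3
  dFN: 0.4
  pC: 0.3
  dC: 4.0
  KT1: 0.5
initial_state:
  P: 1.0
  I: 0.0
  M: 0.0
  F: 0.0
  T: 0.0
  C6: 0.0
  C8: 0.0
  I10: 0.0
  M9: 0.0
  T1: 0.0
  FN: 0.0
  COL: 0.0
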