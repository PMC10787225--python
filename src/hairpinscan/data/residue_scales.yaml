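# Residue scales used by the surrogate propensity backend.
# beta_sheet: Chou-Fasman beta-sheet conformational preference P(beta).
# hydrophobicity: Kyte-Doolittle hydropathy index.
# Nonstandard residues (X, U, B, Z, O) get conservative low values so they
# never seed a high-propensity stretch.
beta_sheet:
  A: 0.83
  R: 0.93
  N: 0.89
  D: 0.54
  C: 1.19
  Q: 1.10
  E: 0.37
  G: 0.75
  H: 0.87
  I: 1.60
  L: 1.30
  K: 0.74
  M: 1.05
  F: 1.38
  P: 0.55
  S: 0.75
  T: 1.19
  W: 1.37
  Y: 1.47
  V: 1.70
  X: 0.50
  U: 1.19
  B: 0.70
  Z: 0.70
  O: 0.74
hydrophobicity:
  A: 1.8
  R: -4.5
  N: -3.5
  D: -3.5
  C: 2.5
  Q: -3.5
  E: -3.5
  G: -0.4
  H: -3.2
  I: 4.5
  L: 3.8
  K: -3.9
  M: 1.9
  F: 2.8
  P: -1.6
  S: -0.8
  T: -0.7
  W: -0.9
  Y: -1.3
  V: 4.2
  X: -3.0
  U: 2.5
  B: -3.5
  Z: -3.5
  O: -3.9
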