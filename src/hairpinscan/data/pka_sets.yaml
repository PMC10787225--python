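# Named pKa tables for Henderson-Hasselbalch net-charge and pI calculation.
# Keys: Nterm/Cterm are the free alpha-amino / alpha-carboxyl groups;
# one-letter codes are ionizable side chains.
emboss:
  Nterm: 8.6
  Cterm: 3.6
  K: 10.8
  R: 12.5
  H: 6.5
  D: 3.9
  E: 4.1
  C: 8.5
  Y: 10.1
lehninger:
  Nterm: 9.69
  Cterm: 2.34
  K: 10.53
  R: 12.48
  H: 6.0
  D: 3.86
  E: 4.25
  C: 8.33
  Y: 10.07
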