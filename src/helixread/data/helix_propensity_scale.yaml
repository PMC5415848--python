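# Helix propensity scale: free-energy cost (kcal/mol) of placing each
# residue in the middle of an alpha-helix, relative to alanine.
# Values are the consensus experimental scale of Pace & Scholtz
# (Biophys J 75:422-427, 1998).  Alanine is the most helix-favoring
# residue (0 by definition); glycine is the least favoring apart from
# proline.
name: pace-scholtz-1998
units: kcal/mol relative to Ala
values:
  A: 0.00
  L: 0.21
  R: 0.21
  M: 0.24
  K: 0.26
  Q: 0.39
  E: 0.40
  I: 0.41
  W: 0.49
  S: 0.50
  Y: 0.53
  F: 0.54
  H: 0.61
  V: 0.61
  N: 0.65
  T: 0.66
  C: 0.68
  D: 0.69
  G: 1.00
  P: 3.16
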