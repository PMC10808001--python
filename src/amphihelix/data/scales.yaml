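# Residue property tables, version 1.
#
# fauchere_pliska: octanol/water transfer free energies (kcal/mol) of
# N-acetyl amino-acid amides, the scale used by HELIQUEST for mean
# hydrophobicity and hydrophobic-moment calculations.
# kyte_doolittle: hydropathy index, used by the built-in FoldIndex-style
# disorder proxy (rescaled to [0,1] as (h + 4.5) / 9).
version: 1
fauchere_pliska:
  A: 0.31
  R: -1.01
  N: -0.60
  D: -0.77
  C: 1.54
  Q: -0.22
  E: -0.64
  G: 0.00
  H: 0.13
  I: 1.80
  L: 1.70
  K: -0.99
  M: 1.23
  F: 1.79
  P: 0.72
  S: -0.04
  T: 0.26
  W: 2.25
  Y: 0.96
  V: 1.22
kyte_doolittle:
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
# Wheel-face membership: residues counted as hydrophobic when projected on
# the 3-11 helical wheel (Fauchere-Pliska value > 0.25, proline excluded
# since it is a helix breaker).  Includes the weak hydrophobics A and T.
face_set: [A, C, F, I, L, M, T, V, W, Y]
# Residues counted toward the "continuous polar/negative residues"
# helix-break rule: uncharged polars plus the negatives.
polar_set: [S, T, N, Q, C, H, D, E]
# Formal side-chain charges at neutral pH (His neutral by default).
charge:
  K: 1
  R: 1
  D: -1
  E: -1
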