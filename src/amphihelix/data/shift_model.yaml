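# Two-state (coil/helix) secondary chemical-shift forward model, version 1.
#
# delta_helix: secondary shift (ppm) of a fully helical residue relative to
# its random-coil reference, per backbone nucleus. These are
# literature-typical magnitudes for stable alpha-helices; they are NOT
# fitted constants of any particular protein. sigma: default per-nucleus
# uncertainties used in the selection chi-square when a shift table does
# not supply its own.
version: 1
delta_helix:
  CA: 2.8
  CB: -0.5
  CO: 1.8
  N: -1.5
  HN: -0.25
sigma:
  CA: 0.4
  CB: 0.5
  CO: 0.4
  N: 0.6
  HN: 0.12
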