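# Statistical-coil sampler configuration, version 1.
#
# Backbone (phi, psi) pairs are drawn per residue from a four-basin
# Gaussian mixture (beta, polyproline-II, right- and left-handed alpha).
# Weights, widths and the two-tier excluded volume are joint calibration
# constants: tuned so a 200-residue chain reproduces Flory random-coil
# dimensions (mean Rg near 44 A, apparent scaling exponent near 0.57 over
# chain lengths 50-400). The short-range tier is a 4.0 A hard core between
# C-alpha atoms; the long-range tier (sequence separation >= 5, where ideal
# helices keep C-alpha pairs beyond 8.8 A) uses a larger soft-core diameter
# standing in for the side-chain bulk a backbone-only model lacks.
# Glycine gets widened basins and more alpha-L; proline has its phi pinned
# near -65 degrees.
version: 1
clash_cutoff: 4.0            # hard core: reject C-alpha pairs closer (A)
clash_min_separation: 3      # ... for sequence separation |i-j| >= this
excluded_volume_cutoff: 8.0  # soft core for |i-j| >= excluded_volume_min_sep (A)
excluded_volume_min_sep: 5
max_residue_retries: 100   # local redraws before a chain restarts
max_chain_restarts: 50     # full restarts before giving up
helical_basin:             # dihedral box defining "helical" flags (deg)
  phi: [-90.0, -30.0]
  psi: [-77.0, -17.0]
basins:
  beta:   {phi_mean: -120.0, phi_sd: 25.0, psi_mean: 135.0, psi_sd: 25.0}
  ppii:   {phi_mean:  -70.0, phi_sd: 15.0, psi_mean: 145.0, psi_sd: 15.0}
  alphaR: {phi_mean:  -63.0, phi_sd: 11.0, psi_mean: -42.0, psi_sd: 11.0}
  alphaL: {phi_mean:   60.0, phi_sd: 13.0, psi_mean:  45.0, psi_sd: 13.0}
weights:
  generic: {beta: 0.295, ppii: 0.265, alphaR: 0.40, alphaL: 0.04}
  G:       {beta: 0.25, ppii: 0.25, alphaR: 0.25, alphaL: 0.25}
  P:       {beta: 0.20, ppii: 0.80, alphaR: 0.00, alphaL: 0.00}
gly_sd_scale: 1.8          # glycine basin widths are scaled by this
pro_phi_mean: -65.0        # proline phi pin (deg)
pro_phi_sd: 7.0
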