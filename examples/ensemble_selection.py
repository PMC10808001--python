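"""Recover a planted helical-propensity profile from synthetic shifts.

Generates noiseless secondary-shift targets from a known profile
(disordered baseline 0.05 with one segment at 0.6), then runs the
iterative statistical-coil + genetic-algorithm selection scheme at desk
scale and compares the recovered profile to the truth.
"""

import numpy as np

from amphihelix.ensemble import DESK_PRESET, iterate_selection, targets_from_table
from amphihelix.synth import synth_shift_dataset

L = 60
profile = np.full(L, 0.05)
profile[24:36] = 0.6

table, _ = synth_shift_dataset(profile, seed=1, noise_sigma=0.0)
targets = targets_from_table(table, L)
result = iterate_selection(L, targets, DESK_PRESET, seed=1)

rmse = float(np.sqrt(((result.recovered_profile - profile) ** 2).mean()))
print(f"desk preset: pool {DESK_PRESET.pool_size}, select {DESK_PRESET.select_m}, "
      f"{DESK_PRESET.iterations} regeneration iterations")
print(f"best chi2 per iteration: "
      f"{[round(x, 1) for x in result.iteration_best]}")
print(f"propensity change per iteration: "
      f"{[round(x, 3) for x in result.propensity_change]}")
print(f"converged: {result.converged}")
print(f"recovered baseline: {result.recovered_profile[:20].mean():.3f} "
      f"(planted 0.05)")
print(f"recovered segment:  {result.recovered_profile[24:36].mean():.3f} "
      f"(planted 0.60)")
print(f"profile RMSE: {rmse:.3f}")
print(f"selected sub-ensemble mean Rg: {result.ensemble_mean_rg:.1f} A")
print("\nEach iteration selects the sub-ensemble whose two-state predicted")
print("shifts best match the targets, then regenerates the pool from the")
print("selected backbone dihedral statistics; the falling chi2 and")
print("propensity change show the ensemble converging onto the planted")
print("local helicity.")
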