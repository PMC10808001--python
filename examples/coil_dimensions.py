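"""Random-coil dimensions of statistical-coil ensembles.

Samples ensembles of several chain lengths and reports the mean radius of
gyration and the apparent Flory scaling exponent.
"""

import numpy as np

from amphihelix.ensemble import sample_coil_ensemble

sizes = {50: 300, 100: 300, 200: 300, 400: 200}
mean_rg = {}
for n, m in sizes.items():
    pool = sample_coil_ensemble(n, m, seed=100 + n)
    mean_rg[n] = float(pool.rg_values.mean())
    print(f"N = {n:3d}: mean Rg = {mean_rg[n]:5.1f} A "
          f"(sd {pool.rg_values.std():4.1f}), "
          f"baseline helicity {pool.helical.mean():.2f}")

ns = np.array(sorted(mean_rg))
rg = np.array([mean_rg[n] for n in ns])
nu = np.polyfit(np.log(ns), np.log(rg), 1)[0]
print(f"\napparent scaling exponent nu = {nu:.3f}")
print("A disordered 200-residue chain shows Rg near 44 A with Flory-like")
print("scaling (nu ~ 0.55-0.6), the signature of an expanded random coil")
print("with excluded volume rather than a compact globule (nu ~ 1/3).")
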