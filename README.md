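# amphihelix

Analysis toolkit for **weak amphipathic 3–11 helical elements in
intrinsically disordered proteins** — the kind of membrane-modulating
elements found in stress-tolerance proteins such as group-3 LEA (late
embryogenesis abundant) proteins. The package covers the full
computational arc of such a study:

* **Detection** of amphipathic elements on the 11-position helical wheel
  (3 turns per 11 residues: residue *i* occupies wheel slot *(3i) mod 11*),
  with helix-break segmentation (proline, glycine runs, long polar/negative
  runs), a three-part amphipathicity test per 7-residue window, and
  stitching into maximal elements.
* **Physicochemical scoring**: mean hydrophobicity *H* and hydrophobic
  moment *µH* on the Fauchère–Pliška scale (HELIQUEST's equations,
  per-residue mean-moment convention), net charge *z*, the discriminant
  factor **D = 0.944·µH + 0.33·z** separating lipid-binding from
  non-binding elements, sliding-window NCPR/FCR charge tracks, and a
  FoldIndex-style disorder proxy.
* **Localization-stratified statistics**: Kruskal–Wallis omnibus tests,
  pairwise Wilcoxon rank-sum with common-language effect sizes and Holm
  adjustment, and summary-statistic t tests.
* **Conformational ensembles**: a statistical-coil sampler (four-basin
  φ/ψ Gaussian mixture, ideal backbone geometry, two-tier excluded
  volume), secondary chemical shifts ΔδCαβ = (δCαobs−δCαrc) −
  (δCβobs−δCβrc), a two-state shift forward model, and ASTEROIDS-style
  genetic-algorithm sub-ensemble selection against chemical-shift and
  radius-of-gyration restraints, with iterative pool regeneration.
* **Instrument-trace formulas**: Langmuir-monolayer compression modulus
  Cs⁻¹ = −A·(dπ/dA), exponential relaxation fits h = A·exp(−R·t),
  heteronuclear NOE ratios I/I₀, fluorescence anisotropy
  r = (I∥ − g·I⊥)/(I∥ + 2g·I⊥), and DSC thermogram baseline/peak
  extraction.
* **Synthetic data** for every input class, with recorded ground truth —
  labelled sequence families with planted 11-periodic elements,
  shift tables from planted helicity profiles, and instrument traces —
  so the whole pipeline is testable offline.

It is written for structural biologists and bioinformaticians studying
disorder-to-helix transitions and protein–membrane interactions.

## Worked example

`examples/detect_elements.py` builds a synthetic 192-residue disordered
construct carrying eight planted amphipathic elements and scores them:

```
sequence synthetic_helea_like: 192 residues, 8 amphipathic elements

element      span  len slots       H    muH    z      D
H1         7-28     22     4   0.127  0.653   -2 -0.044
H2        36-46     11     4   0.127  0.663   -1  0.296
...
H8       178-188    11     4   0.127  0.663   -1  0.296
```

Every element presents its hydrophobic face on 3–5 of the 11 wheel slots
— the signature of a weak amphipathic 3–11 element — and `D` combines
moment and charge into the lipid-binding discriminant.

`examples/ensemble_selection.py` recovers a planted helicity profile
(baseline 0.05, one segment at 0.6) from noiseless synthetic shifts with
the desk-scale iterative scheme (pool 2,000 → select 50, 5 iterations):

```
best chi2 per iteration: [138.5, 29.9, 3.0, 0.8]
recovered baseline: 0.052 (planted 0.05)
recovered segment:  0.598 (planted 0.60)
profile RMSE: 0.013
```

`examples/coil_dimensions.py` shows the coil ensembles' random-coil
dimensions (mean Rg ≈ 44 Å at 200 residues, apparent Flory exponent
ν ≈ 0.56), and `examples/localization_statistics.py` demonstrates the
group comparison on a simulated family: basic-residue fraction and
hydrophobicity separate mitochondrial-type elements from the rest
(p < 1e-30) while the construction-matched hydrophobic moment does not
(p ≈ 0.5).

A command-line interface mirrors the library
(`amphihelix detect|score|compare|ensemble|biophys|simulate`, see
`amphihelix --help`).

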