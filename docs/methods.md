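# Methods

This note documents the models, defaults and numerical choices behind
amphihelix, and what the synthetic-data tests do and do not establish
about real data.

## Amphipathic 3–11 element detection

A 3–11 helix makes 3 turns per 11 residues, so residue offset *i*
(0-based from the element start) projects onto wheel slot *(3i) mod 11*
at angle *i*·(1080/11)° ≈ 98.2° per residue. Detection proceeds in three
stages:

1. **Helix-break segmentation.** The sequence is cut at every proline,
   every run of ≥ `g_run_min` glycines (default 2 — a single glycine is
   tolerated, a "continuous" run is not), and every run of ≥
   `polar_run_min` polar/negative residues (default 4; the polar set is
   {S, T, N, Q, C, H} ∪ {D, E} — positives and hydrophobics are excluded
   by construction). Break residues belong to no segment, so no element
   can contain a proline.
2. **Window test.** Every 7-residue window inside a segment (7 residues
   is the minimum amphipathic length, two turns of the 3–11 wheel) must
   (a) contain 2–5 hydrophobic-face residues, (b) cluster those residues
   within a wheel arc ≤ 180°, and (c) carry a window hydrophobic moment
   ≥ 0.2 at the wheel angle. These three constants operationalise
   "apolipoprotein-like amphipathicity" and are all exposed in
   `DetectionParams`; the defaults were chosen so that detected elements
   show 3–5 distinct hydrophobic wheel slots.
3. **Stitching and the slot filter.** Valid windows that overlap or abut
   merge into maximal elements; elements whose face residues occupy
   fewer than 3 or more than 5 distinct slots are discarded (the 3–11
   signature — a continuous but narrow hydrophobic stripe).

Detection is deterministic and is verified exhaustively against a
brute-force enumeration oracle (independent break scanning, trigonometric
moment sums, arc enumeration, coverage components) on random sequences.

Note that the *number* of elements is not monotone in the window
threshold: tightening `muH_min` can split one long element into two. The
monotone invariant is the residue coverage, which only shrinks.

### Residue tables

The hydrophobicity scale is Fauchère–Pliška (octanol/water transfer free
energies, the scale HELIQUEST uses), stored in a versioned YAML data file
and overridable. The wheel-face set {A, C, F, I, L, M, T, V, W, Y} is
"scale value > 0.25, proline excluded", which deliberately includes the
weak hydrophobics alanine and threonine that these elements are enriched
in. Charges are K/R = +1, D/E = −1, histidine neutral (neutral pH);
terminal charges are not counted.

## Physicochemical scores

* *H* is the plain mean of scale values.
* *µH* = (1/N)·|Σ h_i (cos iδ, sin iδ)| — the per-residue mean moment
  (HELIQUEST's normalisation). Two angles are supported: δ = 100°
  (α-helix, used for reported properties and for D) and δ = 1080/11°
  (3–11 wheel, used for slot/arc geometry during detection). Both are
  reported on every element.
* *D* = 0.944·µH + 0.33·z, computed from the 100° moment by default.
* NCPR/FCR use a 10-residue sliding window.
* The built-in disorder proxy is FoldIndex-style:
  FI = 2.785·⟨H_KD,norm⟩ − |⟨NCPR⟩| − 1.151 over a 51-residue window,
  with Kyte–Doolittle hydropathy rescaled to [0, 1] and a pseudo-disorder
  score clamp(0.5 − FI/2, 0, 1). It is a stand-in used when no external
  per-residue disorder track is supplied; supplied tracks are preferred.

## Group statistics

The omnibus across localization groups is the Kruskal–Wallis rank sum
test with midrank tie correction; p-values come from the χ² reference
(k−1 df), from exhaustive permutation enumeration when the total sample
is ≤ 10, or from Monte-Carlo permutation on request. Pairwise contrasts
are two-sided Wilcoxon rank-sum tests (exact null when both groups are
≤ 10 and tie-free), reported with the common-language effect size
CLES = [#(x>y) + ½#(x=y)]/(n₁n₂) and the plain difference of medians
(not Hodges–Lehmann). Holm adjustment spans all pairs × properties as a
single family; raw p-values are always reported alongside. The t test
accepts summary statistics (mean, SD, n) or raw vectors, pooled or
Welch. The basic-residue fraction compared across groups is #(K,R)/length.

## Statistical-coil ensembles

Backbones are built atom-by-atom (N, Cα, C) with ideal bond geometry and
trans peptides (ω = 180°); dihedrals are drawn per residue from a
four-basin Gaussian mixture (β, PPII, αR, αL), glycine widened, proline
φ-pinned. Chains grow under a two-tier excluded-volume constraint on
Cα pairs with sequence separation ≥ 3: a 4.0 Å hard core at separations
3–4 and a calibrated 8.0 Å soft core at separations ≥ 5 — the larger
diameter stands in for the side-chain bulk a backbone-only model lacks,
and ideal α-helices (whose i,i+5 Cα pairs sit at ~8.9 Å) remain
admissible. A clash triggers a local redraw of the offending dihedrals
(capped), then a whole-chain restart; retained conformers never violate
the constraint.

All mixture weights, widths and cutoffs live in
`data/coil_basins.yaml`. The generic weights (β .295, PPII .265, αR .40,
αL .04) together with the excluded volume were calibrated once so a
200-residue chain reproduces Flory random-coil dimensions: mean
Rg ≈ 44 Å with an apparent scaling exponent ≈ 0.56–0.58 over chain
lengths 50–400. The realized per-residue helicity of the calibrated coil
is ≈ 0.30 (clash resampling depletes compact helical draws below the
nominal αR weight), within the range expected for disordered chains.
"Helical" flags are defined by a dihedral box, φ ∈ [−90°, −30°],
ψ ∈ [−77°, −17°], configurable.

### Shift forward model and selection

Random-coil reference shifts are always an input; none are hard-coded
(the synthetic generator uses generic reference values for its own
tables). Ensemble-averaged shifts use a deliberately simple two-state
model: δpred = δrc + p_helix·Δ_helix per nucleus, with literature-typical
full-helix offsets (Cα +2.8, Cβ −0.5, CO +1.8, N −1.5, HN −0.25 ppm)
stored in `data/shift_model.yaml`; predictions are exactly linear in
helical propensity. ΔδCαβ is evaluated literally, with glycine rows
carried as flagged Cα-only values and missing observations propagated as
absent, never zero.

Selection is a genetic algorithm over index multisets of fixed size M:
fitness is the χ² of sub-ensemble-averaged predicted shifts against the
targets (plus an optional ((⟨Rg⟩ − Rg₀)/σ)² restraint), with tournament
selection (size 3), one-point crossover, 2%-per-locus mutation, single
elitism (hence non-increasing best fitness), and a 50-generation stall
stop. The iterative scheme re-estimates per-residue basin frequencies
from the selected conformers, regenerates a biased pool from them
(floored at 1e-3 per basin and renormalised), mixes in fresh coil
conformers, and reselects; convergence is reported as the mean absolute
change in recovered propensity between iterations (default tolerance
0.02 — the convergence criterion is a design choice, reported with every
run). Scheme sizes ship in two presets: the full-scale preset (pool
10,000 → 200; regenerate 8,500 + 1,500; 9 iterations) and a desk preset
(2,000 → 50; 1,700 + 300; 5 iterations) used by the tests; the recovery
benchmarks run on 60-residue chains so the whole suite stays fast. The
Rg-restrained variant defaults to a 5,000 → 50 scheme and reduces
exactly to the unrestrained run when the restraint weight is zero. SAXS
curves are not predicted; the global-dimension restraint acts on Rg
directly.

## Instrument-trace analyses

* Cs⁻¹ = −A·(dπ/dA): derivative by central differences (numpy.gradient)
  on the optionally Savitzky–Golay-smoothed trace; accuracy against
  analytic derivatives of smooth synthetic isotherms is < 2% away from
  the endpoints. Band means (e.g. 25–35 mN/m) are available.
* Exponential decays are fitted by nonlinear least squares initialised
  from a log-linear regression; non-decaying series are fitted anyway and
  flagged. Synthetic benchmarks use the measurement grids of typical
  relaxation experiments (16 delays 8.5–271 ms; 11 delays 10 ms–2 s).
* Anisotropy uses r = (I∥ − g·I⊥)/(I∥ + 2g·I⊥) with default g = 1.171.
* DSC thermograms subtract the mean of the trailing 15 points (a region
  beyond the transition) as baseline; Tm is the grid temperature of the
  global maximum (so its resolution is the grid spacing) and secondary
  transitions are prominence-based local maxima (threshold 10% of the
  main peak). Boundary maxima are flagged unreliable. Units are declared
  per trace; nothing converts implicitly.

## Synthetic data: what it emulates, and what it does not

Sequence families consist of a polar/charged-rich disordered background
(iid draws from a disorder-biased composition with frequent prolines and
very low hydrophobic content, so the background carries essentially no
amphipathic signal) interleaved with planted 11-periodic elements
separated by explicit breakers (P or GG). Planted lengths are whole
repeats (11/22/33), which keeps the hydrophobic moment of the two
composition variants matched *exactly* at every planted length: the
mitochondrial/chloroplast variants raise the K/R fraction by ≈ 0.3 and
lower mean hydrophobicity by ≈ 0.25 while matching the base unit's
per-repeat µH to < 5·10⁻⁴ with sign-balanced residuals across the
variant pool. The sign balancing matters: rank tests resolve arbitrarily
small but systematic value offsets at large sample sizes, so a merely
"small" µH mismatch would still light up a Kruskal–Wallis test.
Mutations are class-preserving within near-iso-hydrophobic alphabets
({L,I,F}, {M,V}, {K,R}, {D,E}) so planted truth survives. Secretory
sequences carry an N-terminal hydrophobic stretch prepended outside the
shared length budget (uniformly hydrophobic, hence invisible to the
2–5-face window test).

What passing tests show: the detector finds designed 3–11 elements and
nothing in designed nulls; the statistics reject planted composition
shifts with high power and stay at the nominal level on
moment-matched nulls; the selection scheme recovers planted helicity
profiles from its own forward model. What they do not show: performance
on real proteomes (real disordered backgrounds are not iid and real
elements are not exact repeats), the accuracy of the two-state shift
model against measured shifts, or the realism of the coil ensemble
beyond its calibrated global dimensions.

The designed HeLEA1-like construct used in the examples and tests is a
synthetic stand-in: a ~200-residue disordered chain with exactly eight
planted elements of varied lengths mirroring the structure of the
natural analysis target. Runs on a real sequence use the same `detect`
interface on a user-supplied FASTA.

## Degenerate inputs and tie-breaks

Empty sequences segment to nothing; all-identical statistical samples
return H = 0, p = 1 by convention; zero-variance equal-mean t tests
return p = 1 and unequal means raise; windows are scanned strictly left
to right and nothing in detection draws random numbers; every stochastic
component (sampler, GA, generators) flows through one seeded NumPy
generator per call.

## Known limitations

* The coil sampler has no residue-specific φ/ψ database beyond the
  G/P special cases; composition-dependent dimensions are not modelled.
* The shift model ignores nearest-neighbour and temperature corrections;
  reference tables must already include them.
* The GA selects multisets (a conformer may repeat within a selection).
* Cs⁻¹ endpoints inherit one-sided difference error; report interior
  points.
* The disorder proxy is a coarse stand-in for dedicated predictors and
  is labelled as such wherever it is used.
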