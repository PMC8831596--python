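# Methods

This note documents the models, parameter choices and known limitations of
flexfold. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

The target systems are C5-symmetric membrane-protein assemblies whose
intracellular domains are too flexible for crystallography or cryo-EM.
Solution NMR supplies per-residue observables (intensity ratios under
paramagnetic labelling, NOESY cross peaks, IPAP splittings, amide-shift
temperature series, relaxation decays, saturation-transfer pairs); pulsed
ESR (DEER) supplies inter-subunit spin-label distance distributions. The
package converts these observables into distance restraints, folds one
subunit under a C5 replication constraint against a restraint-augmented
coarse-grained score, and validates the resulting ensembles with held-out
restraints and structural analytics.

## Observable → restraint models

**PRE.** The measured intensity ratio follows
`I/I0 = R2dia · exp(−R2sp · t_evol) / (R2dia + R2sp)` with
`R2dia = π · Δν_dia`; the rate is inverted by bracketed Brent root finding
(the map is a bijection of (0, 1] onto [0, ∞)). Distances follow the
Solomon–Bloembergen relation
`r = [(K/R2sp) · (4τc + 3τc/(1 + ω_H²τc²))]^(1/6)` with the standard
nitroxide constant `K = 1.23e-32 cm⁶ s⁻²`. Ratios at or above the ceiling
(0.85) yield lower-bound-only restraints at 23 Å, ratios at or below the
floor (0.10) upper-bound-only restraints at 12 Å, and intermediate ratios
two-sided restraints with a ±4 Å band. The default conversion parameters
(τc = 33.23 ns, t_evol = 52.83 µs, 700 MHz) were solved so that, at the
toy 20 Hz diamagnetic linewidth, the ceiling and floor ratios cross over
*exactly* at the 23/12 Å bounds — otherwise the bound rules contradict the
distance conversion and a structure generating the data would violate its
own restraints. τc of ~33 ns is a plausible tumbling time for a
detergent-solubilised pentamer; all values are configuration keys.

**DEER.** One label per subunit of a C5 ring gives exactly two unique
inter-label distances with `d_diag/d_adj = 2·cos 36°` (the golden ratio).
Distributions are decomposed by a two-Gaussian least-squares fit (lmfit)
initialized from detected peaks, with the pentagon ratio used to
initialize — and, for single-mode distributions, to infer — the diagonal
mode (flagged `diagonal_inferred`). Mode pairs become harmonic restraints
with weight 1/width². Spin-label positions are modelled as pseudo-label
sites 5 Å from the Cα along the outward bisector of the local trace (for
full-atom structures: 3.5 Å beyond Cβ along Cα→Cβ).

**NOE / temperature coefficients / RDC / relaxation.** NOE classes map to
flat-bottom bounds (strong/medium/weak → 3.5/4.5/6.0 Å upper, 1.8 Å lower;
a configurable table). Amide-proton temperature coefficients are
ordinary-least-squares slopes in ppb/K; residues with |slope| < 4.5 ppb/K
are flagged hydrogen-bonded (the magnitude criterion is used because amide
coefficients are conventionally negative). RDCs are differences of IPAP
¹⁵N splittings converted at the ¹⁵N frequency (γN/γH = 0.10136767); they
are used for secondary-structure validation and forward checks only, not as
folding restraints. R₁/R₂ come from `A·exp(−Rτ)` fits with a deterministic
log-linear initializer; hetNOE is the saturated/unsaturated intensity ratio
with propagated uncertainty.

## Scoring

`S_total = S_physics + S_knowledge + S_DEER + S_PRE + S_NOE` (unit class
weights by default; lower is better; only ranking matters). The physics
stand-in works at Cα resolution: virtual-bond term (target 3.8 Å, k = 5),
pseudo-angle penalty below 75° (k = 20; no straightness penalty — extended
coil is legitimate), and soft-sphere repulsion below 4.0 Å (k = 10,
nonbonded intra-chain pairs and all inter-chain pairs). The knowledge
stand-in biases fully-helical four-residue windows toward the ideal
Cα pseudo-dihedral of +50° (k = 5). Restraint terms: harmonic for DEER,
logistic sigmoids (steepness 2 Å⁻¹, value 0.5 at the bound) for PRE, and
flat-bottom for NOE. On an exact-C5 pentamer every term equals five times
its unique-instance value, which is how the compiled scorer evaluates it; a
pure-numpy reference path over explicit chains is kept and the two are
held to agreement by parity tests.

Because the sigmoid PRE potential is bounded, it is blind beyond ~1 Å of
its bounds. The Monte Carlo sampler therefore adds a weak quadratic
*guidance* term on bound violations (k = 0.02 Å⁻²) to the acceptance
energy only; all reported and ranked scores are the plain `S_total`.

## Sampling and the iterative protocol

One asymmetric unit is sampled; helical segments (from chemical-shift
annotation) are rigid bodies, loop residues carry pivot and crankshaft
hinges, and the whole subunit takes rigid-body moves. All moves preserve
virtual-bond lengths exactly. Annealing uses a geometric temperature
ladder with move amplitudes shrinking as √(T/Tmax) (fixed-amplitude mode is
available and used for the acceptance-rate sanity test). Every trial
conformation is scored as the C5 pentamer about the fixed symmetry frame.

The iterative protocol generates a pool per round (desk-scale default 40;
production-scale 1000 is a flag), ranks by `S_total`, clusters the top 10
(100 at production scale) by greedy leader clustering at a 3 Å Cα-RMSD
cutoff — deterministic, and every member is provably within the cutoff of
its representative — and reseeds the next round from cluster
representatives diversified through geometry-preserving moves. The
incumbent best model is carried over (elitism; can be disabled), making the
best score non-increasing. Convergence is declared when the best score
improves by less than 10 score units (≈ the scatter among top-pool models)
over a 2-iteration window *and* the top representative moves by less than
half the cluster cutoff; the rule is a pure function of the iteration log.
Selected models then pass through a cold-annealing + hill-descent
refinement stage that never increases the score.

**Templates and handedness.** Distance restraints are invariant under
reflection: a quasi-mirrored ring whose helices are rebuilt right-handed
satisfies every distance within tolerance, and at coarse-grained resolution
nothing else in the data distinguishes the two enantiomeric basins — in
experiments this ambiguity is broken by homolog templates and L-amino-acid
stereochemistry. The protocol therefore accepts first-round-only template
structures, exactly as integrative determinations of these receptors use
homolog starting models. The synthetic bundle ships a "homolog" template:
the ground truth diversified by 150 geometry-preserving moves, typically
10–17 Å pentamer Cα RMSD away — far enough that recovery is a genuine
refinement problem, near enough to select the correct handedness basin.

## Synthetic generator (the study conditions)

The toy subunit has 60 residues: an 18-residue amphipathic helix, a
24-residue loop, and an 18-residue long helix running down the pore,
assembled at ring radius 20 Å into an exact C5 pentamer. The loop is a
self-avoiding bridge with exact bond closure, turn angles capped at ~115°,
and a waypoint route that (i) detours to the rim and (ii) anchors its later
third within 8 Å of the long helix — emulating the anchored "B"-shaped
double-loop architecture of real intracellular domains. Builds that clash
across chains are rejected and retried from derived sub-seeds.

Forward models are exact inverses of the restraint derivations, so all
round trips close to numerical precision at zero noise (PRE ≤ 1e-6 Å, RDC
≤ 1e-9 Hz, relaxation rates ≤ 1e-6 relative, hydrogen-bond flags exactly).
PRE tables are emitted for three label sites (residues 10, 30, 52), both
intra-subunit and — emulating the mixed-labelling experiment — for the
adjacent subunit; DEER distributions are emitted for all three labels
(5 adjacent + 5 diagonal pairs ⇒ equal mode weights). Dynamics use the
two-timescale model-free spectral density with S² = 0.85/τe = 20 ps in
helices and S² = 0.30/τe = 1 ns in loops, and a toy tumbling time
τm = 5 ns chosen so that flexible-loop residues show the reduced-to-negative
heteronuclear NOEs characteristic of fast backbone motion while helices
stay positive; at the ~15 ns tumbling of a real micelle-bound pentamer the
NOE of an S² = 0.3 residue would remain positive, so the toy deliberately
compresses timescales. Temperature-series slopes are drawn from
(−4.4, −0.5) ppb/K for hydrogen-bonded residues and (−9.0, −4.6) otherwise;
NOE contacts are Cα pairs within 5.5 Å classed by distance (which excludes
ideal-helix i,i+4 Cα pairs at 6.2 Å; i,i+3 contacts carry the helical
signal).

What the generator does *not* emulate: spectral overlap and peak-picking
ambiguity, incomplete assignments, label-linker flexibility and
ensemble-averaged ⟨r⁻⁶⟩ effects, membrane/micelle anisotropy, and
differential restraint quality across conditions. Passing recovery tests
therefore demonstrates the correctness and internal consistency of the
pipeline machinery at desk scale, not the information content of any real
data set.

## Problem sizes

The recovery experiment runs the protocol at desk scale — 60
residues/subunit, pool 40, top 10, at most 6 iterations, 5 protocol seeds
with a 10% PRE holdout — for which a full run takes on the order of a
minute per seed on one CPU. Production-scale pool sizes (1000/100) are
plain configuration values on the same code path.

## Numerical choices

- PRE inversion: Brent bracketing with xtol 1e-12; exponent guarded.
- Two-Gaussian DEER fits: peak-detection initialization, widths bounded
  below by a quarter grid step; single-mode fallback by area/separation
  tests (second mode < 5% area or unseparated).
- Exponential fits and the DEER mixture use lmfit; failures return explicit
  non-converged flags, never silent defaults.
- Superposition via quaternion-based least squares
  (`scipy.spatial.transform.Rotation.align_vectors`), checked in tests
  against a dense random-rotation search oracle.
- Symmetry-axis estimation: SVD plane normal of the five chain centroids,
  sign fixed toward +z (ties toward +x, then +y); degenerate (collinear)
  geometry raises.
- Pore profiling: at each axis coordinate the in-plane centre maximizing
  the clearance min(|c − atom| − vdW) is found by 9-start Nelder–Mead
  (axis point + 8 seeded perturbations), radius clamped at 15 Å; Bondi-type
  vdW radii are fixed in `structio.VDW_RADII` since pore radii depend on
  them. The scheme is an approximation to full Monte Carlo pore tracing;
  profiles in narrow, strongly off-axis channels may be slightly
  conservative.
- Secondary structure: Kabsch–Sander-style electrostatic hydrogen-bond
  energy `27.9·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond below
  −0.5 kcal/mol; consecutive i→i+4 turns ⇒ H, i→i+3 ⇒ G, isolated turns ⇒
  T, else C. Missing amide hydrogens are placed 1.01 Å from N along the
  C(i−1)/Cα bisector. Disorder fractions count {T, C}; 3₁₀ counts as
  ordered. Assignment-method dependence of disorder fractions is a known
  caveat: different assignment algorithms differ by several percentage
  points on borderline turns.
- Q-factors: two-sided (targeted) restraints contribute (d0, r_calc) with
  r_calc the ensemble-mean distance; bound-only and flat-bottom restraints
  contribute only when violated, with r_exp set to the violated bound. A
  class whose bound restraints are all satisfied has Q = 0.
- The compiled (numba) scorer is held to 1e-8 agreement with the pure-numpy
  reference path by tests; without numba the package falls back to the
  numpy path.

## Known limitations

- Cα-only resolution: no side chains, no all-atom packing or
  Ramachandran-level validation; the physics/knowledge terms are stand-ins
  for a full force field and only their ranking behaviour is relied on.
- Handedness is supplied by the first-round template, not the data; without
  a template the protocol converges equally well (by score and free-set Q)
  to either enantiomeric basin.
- PRE conversion assumes a single effective correlation time and
  single-conformer distances; no ⟨r⁻⁶⟩ ensemble averaging during
  refinement.
- DEER distributions are consumed as given; raw time-trace inversion
  (background correction, regularization) is out of scope.
- The convergence rule is a pragmatic plateau detector; it reports, not
  proves, convergence.
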