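# Methods

This note records the models the package implements, the defaults it ships,
what the synthetic generators do and do not emulate, and the numerical and
design choices made where the literature leaves the details open.

## Paired alignments and paralog matching

Alignments are gapped sequences over the 20 amino acids plus `-`; species
tags come from the `OS=` header field when present, else from the UniProt
mnemonic suffix (`NED1_ARATH` → `ARATH`); rows without a parseable tag are
excluded from pairing.  Gap-run filtering removes rows whose longest
contiguous run of `-` (terminal runs included) exceeds `ceil(f·L)`; the
boundary is inclusive (a run of exactly `ceil(f·L)` survives), a documented
choice since published descriptions of the 20%/50% rules do not state the
rounding.  The filter is idempotent and monotone in `f`.

Paralog matching is progressive: species with exactly one sequence in each
family are paired first and anchor the process; remaining species are
processed in order of increasing paralog count, scoring each candidate
(a, b) pair by its best joint identity to any already-paired row,
`S[a,b] = max_m pid(a, A_m) + pid(b, B_m)`.  This score is deliberately
non-separable: it asks whether *this* A-paralog and *this* B-paralog
resemble the A- and B-halves of the *same* existing paired row.  Within a
species the assignment maximizing total score is exact (Hungarian) up to
6×6 and greedy beyond, with ties broken toward the lowest row indices.
Each species contributes `min(#A, #B)` rows.  When no single-copy species
exists the first multi-paralog species is paired by row order — the global
lineage correspondence is genuinely unidentifiable in that case (see the
generator discussion below).

## Mean-field DCA

Defaults: `q = 21` with the gap treated as a coupled state and used as the
reference state of the `(q−1)`-dimensional reduction; reweighting identity
threshold 0.8; pseudocount `λ = M_eff` (pseudocount weight one half).  These
are the field-standard mean-field settings; the upstream literature this
pipeline follows does not print its values, so they are declared here rather
than inferred.  Couplings come from one inversion of the
`L(q−1) × L(q−1)` connected-correlation matrix, which `λ > 0` keeps
non-singular; `λ = 0` on degenerate data raises an error that suggests
raising the pseudocount.

Direct Information uses the standard two-site construction: auxiliary fields
are fixed-point iterated (at most 200 sweeps) until both marginals of
`P_dir(a,b) ∝ exp(e_ij(a,b)) h̃_i(a) h̃_j(b)` match the single-site
frequencies within 1e-4; non-convergent pairs get `DI = NaN`, are excluded
from ranking and counted in the log.  DI is clipped at zero against
round-off.  Ranking of inter-domain pairs is by raw DI, descending, ties
broken by ascending `(i, j)`; average-product correction is available but
off by default because the workflow ranks raw DI.  No minimum sequence
separation is applied across the domain boundary (interface prediction *is*
the inter-domain question); intra-domain ranking is out of scope.

The brute-force check for the DI computation exploits that at `q = 2` the
two-site model is closed-form: with both marginals fixed, the joint table
has a single free parameter pinned by the coupling's odds ratio, so DI
follows from a quadratic — no iteration, fully independent of the fixed
point.

## Enrichment and surface filtering

The right-tailed hypergeometric tail is computed with exact integer
combinatorics (`math.comb` over `Fraction`), so the only error is the final
float rounding; no normal approximation is involved anywhere.  The universe
`N` is all inter-domain residue pairs between the two regions present in the
model, with unmodeled residues excluded from `N`, `K` and `k` alike — one
consistent universe for predictions and contacts.  Retention is `p ≤ α`
(inclusive) at `α = 0.2` with no multiple-testing correction, mirroring the
source workflow; three significance tiers (`p ≤ 0.05`, `≤ 0.1`, `≤ 0.2`)
are reported alongside.  Combined SASA is the sum over the pair's two
residues computed in the context of the full complex, and the threshold is
strict (`> 100 Å²`, a combined value of exactly 100 is removed).  SASA is
Shrake–Rupley via biotite (probe 1.4 Å, 1000 Fibonacci points per atom,
element-keyed single-atom radii); Cα-only bead models cannot be
SASA-filtered and raise a capability error.

## Crosslink mapping

Crosslink tables are residue-pair exports (4-column or xiFDR `PepPos`
dialect); unordered duplicate pairs collapse with their multiplicity
retained.  Positions are 1-based in the expressed construct; per-protein
offsets translate to author numbering.  Satisfaction is strict
(`Cα–Cα < 35 Å`), matching the usual reading of the BS3 bound.  In
multi-copy assemblies each record takes the chain-copy pairing minimizing
the distance — the standard XL-MS convention — and the chosen copies are
recorded.  Unknown proteins (contaminants from expanded searches) pass
through with `unmapped-protein` status rather than erroring.  Assembly
comparison reports, per record mapped in both models, the distance delta;
"shorter in the second model" means strictly negative delta.

## Structure handling

Structures wrap a biotite `AtomArray`: first model of multi-model files,
highest-occupancy altlocs, author residue numbers authoritative.  Residues
without a Cα are retained but flagged and excluded from distance
operations.  Contacts use Cα–Cα or minimal heavy-atom distance at a
configurable cutoff (8 Å default, the DCA-literature convention for true
positives).

## The Gō-model docking engine

One bead per residue at the Cα position, reduced units (bead mass 1,
`ε = 1`, lengths in Å): harmonic bonds `k_b = 100 ε/Å²`, harmonic angles
`k_a = 20 ε/rad²`, 1×/3× cosine dihedrals `k_d = 1 / 0.5 ε`, native
contacts as 12-10 wells with `σ` the native distance, excluded volume
`(σ_ex/r)¹²` with `σ_ex = 4 Å` between non-excluded pairs.  Native contacts
are intra-chain pairs (`|i−j| > 3`) within the cutoff; inter-chain native
contacts are off by default so that inter-body attraction comes only from
the DCA restraints — with them on, docking would trivially succeed and the
no-restraint negative control would be meaningless.  DCA restraints are the
same 12-10 well at a target distance (8 Å default, consistent with the
contact definition) with depth `ε_DCA = 1` by default; a subset selector
supports restraining with, e.g., 5 of the top 10 pairs.  Every bonded,
contact and restraint pair is excluded from the excluded-volume sum.

Dynamics are BAOAB-discretized Langevin; at zero friction the scheme is
velocity Verlet and conserves energy (the drift test holds it to <0.1% over
1e5 steps).  Two numerical guards matter: (i) angle and dihedral terms whose
*native* geometry is collinear (within 0.1 rad of θ = π) get zero force
constants, because their gradients are singular there — straight toy bead
chains would otherwise be unintegrable; (ii) during integration, an angle
whose instantaneous geometry passes within `sin θ < 1e-4` of collinearity
skips that step's force contribution.  Energy divergence (|U| > 1e8) aborts
the run with advice to reduce the timestep.

The receptor is position-restrained by weak per-bead tethers
(`k = 0.02 ε/Å²`, ~5 Å thermal fluctuation at `T = 0.5`) so docking is
ligand-dominant.  An optional flat-bottom spherical wall confines the system
— the stand-in for the finite cell every real simulation has; without any
boundary a freely diffusing ligand escapes to infinity and the capture
probability from a finite start is below one regardless of simulation
length.

## Synthetic data: what it emulates, what it does not

The Potts sampler draws sequences by Gibbs sampling (sequential site sweeps,
burn-in 1000 sweeps, thinning 10) from a two-domain model with planted
diagonal couplings `e(a,b) = s·𝟙[a=b]` on chosen inter-domain pairs.  The
gap is alphabet state 0, so sampled sequences contain isolated gaps at the
uniform rate; additional contiguous gap runs can be inserted post-hoc to
emulate alignment-style indel blocks without modeling indel evolution.

Paralogs are modeled as *lineages*: each paralog slot has its own ancestor
(a widely spaced Gibbs record) and every species' copy is that ancestor plus
k point mutations (default 10).  This is the weakest structure under which
paralog matching is a well-posed problem: lineages must be distinguishable
across species, and *single-copy species must exist* to anchor which
A-lineage goes with which B-lineage — with two paralogs in every species the
two global correspondences are exactly symmetric and no algorithm can pick
the right one.  The paralog benchmark therefore mixes 25 single-copy and 25
two-paralog species.  What the generator does not emulate: phylogenetic
correlation between species, realistic indel processes, heterogeneous
conservation across sites, or side-chain atoms.  Passing the recovery
benchmarks therefore demonstrates correctness of the inference chain on
well-specified ground truth, not performance on real, phylogenetically
structured alignments, where effective depths are lower and paralogy is
messier.

Toy complexes are bead chains with exact 3.8 Å virtual bonds, either
straight (simplest fixtures) or planar zig-zag (non-degenerate angles and
dihedrals, required for an active bonded force field).  Interface pairs are
realized *exactly* by placing each constrained chain as a congruent
translated copy of its partner's template, which requires all pairs between
two chains to share one residue-index offset (otherwise a
constructive-failure error is raised); a chain carrying a single pair is
instead rotated 45° about the paired bead so that only the planted pair sits
at the target distance.  Full-register placement implies every same-offset
bead pair sits at the target distance — by construction, not by accident.

Synthetic crosslink tables draw true records from inter-chain pairs within
the distance bound and decoys from pairs beyond a configurable floor,
without replacement, with labels retained for evaluation.

## Benchmark conditions

The three benchmarks in `coevodock.benchmark` fix the study conditions used
by both the test suite and `scripts/acceptance.py`:

* **Planted-coupling recovery** — q = 21, two 30-column domains, ten planted
  pairs at strength 1.5, 5000 sequences; scored as top-10 inter-domain DI
  precision, median over five seeds.  Depths of 2000–5000 are chosen for
  statistical power (real per-family depths vary widely and are not the
  point of the benchmark).
* **Paralog matching** — 50 species (25 single-copy anchors + 25 with two
  paralogs), lineage divergence 10 mutations; scored as the fraction of
  ground-truth pairings recovered, median over five seeds.
* **Restrained docking** — two 14-bead zig-zag chains with a ten-pair native
  interface at 8 Å; receptor tethered; ligand placed at 25 Å center-of-mass
  separation inside a 28 Å flat-bottom wall; `T = 0.5`, `dt = 0.002`,
  friction 0.05, restraint depth 2 ε (4 k_BT, so restraints dominate thermal
  noise), 5×10⁵ steps.  Scored as the mean fraction of restraint pairs
  within 1.2× target over the final 10% of snapshots; the negative control
  runs the identical system without restraints.  The 25/28 Å geometry scales
  the search problem to what five sub-10-second runs can resolve; the
  60 Å placement convention remains the default of `initialize_separation`
  for full-scale use.

## Known limitations

* Mean-field DCA only; pseudolikelihood and Boltzmann-machine inference are
  out of scope, and no claim of numerical equality with any particular
  published DCA implementation is made.
* The docking engine is a Cα model with SMOG-conventional functional forms,
  not a GROMACS-compatible reimplementation; exported topology files are a
  plain-text Gromos87-style dialect for inspection, not for ingestion by
  GROMACS.
* The toy-complex constructor only realizes interface sets expressible by
  congruent translation (plus the single-pair rotation); arbitrary pair
  geometries are rejected rather than approximated.
* `filter_max_gap_run` counts only `-`; alignments using `.` for gaps are
  normalized on read, but externally constructed `Msa` objects are not.
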