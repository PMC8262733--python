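# Methods

This note documents the models, algorithms, parameters and design choices in
`heterodock`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting and assumptions

The pipeline predicts the structure of a two-chain protein complex from the
structures of its subunits by *template transfer*: if a known structure
contains two parts (two chains of a hetero- or homo-oligomer, or two domains
of a monomer) that each resemble one subunit, the relative orientation of
those parts is a plausible binding mode for the target. Assumptions:

- rigid subunits — each subunit is superposed as a rigid body; no backbone
  or side-chain relaxation is performed and delivered models are unrefined;
- representative-atom geometry — every measure (alignment, TM-score, clash,
  contact, buried area, CAPRI metrics) operates on CA atoms (CB additionally
  for interface extraction), keeping the pipeline side-chain-free;
- subunit input frames are arbitrary — every score is invariant to rigid
  motions of either input subunit, since subunits may come from independent
  monomer predictions with meaningless mutual orientation;
- subunits under 1000 residues (configurable guard).

## Superposition and TM-score

Kabsch superposition is computed via SVD of the cross-covariance with the
determinant correction that excludes reflections; inputs with fewer than 3
points or exactly collinear points are rejected as degenerate. The TM-score

    TM = max_T (1/L_norm) Σ_i 1/(1 + (d_i(T)/d0(L_norm))²),
    d0(L) = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å,

is maximized by fragment seeding plus iterative close-pair refinement:
seeds are contiguous windows of the correspondence with lengths L, L/2, L/4,
L/8 (minimum 4) at offsets every L/16; each seed is refined for up to 20
rounds of "superpose on pairs with d < cutoff, rescore all pairs", with the
cutoff shrinking linearly from d0 to 3 Å over the first ten rounds (grown in
0.5 Å steps whenever fewer than 3 pairs survive); the best score over all
seeds and rounds is returned together with the transform achieving it.

Normalization conventions: subunit-to-template scores use the target subunit
length; the interface score uses the pooled count of target residues mapped
to template interface positions; the complex score uses the total residue
count. Swapping reference and mobile chains changes the score only through
floating-point noise (< 1e-6).

Known limitation: for heavily distorted pairs (coordinate noise ≳ 1.2 Å on
30–60-residue chains) the score landscape becomes multimodal and the seeded
search — like any fragment-seeded protocol, including an exhaustive-window
oracle — may settle ~1e-3 below the true optimum. At the noise scales the
synthetic benchmarks use (0.3–0.6 Å) the search matches an exhaustive-seed
oracle to ~1e-6–1e-4.

## Alignment

*Sequence path.* Needleman–Wunsch global alignment with BLOSUM62 and affine
gaps (open 11, extend 1), X scored 0 against everything; identity is
matches over aligned columns. An optional reader ingests HHsearch `.hhr`
summary lines (id, probability, query/template ranges mapped gaplessly) for
users who run a profile search externally; the built-in path otherwise ranks
candidates by raw alignment score.

*Structure path.* Sequence-independent alignment in the TM-align style:
from each gapless threading offset (about two dozen, spaced (n+m)/24), iterate
(a) dynamic programming over S_ij = 1/(1+(d_ij/d0)²) with a constant gap
penalty of 0.6 per gap column, ties broken toward the diagonal, and (b)
re-superposition on the new correspondence, until the correspondence is
stable or 30 rounds. Seeds are ranked by a cheap single-superposition score;
the full TM-score optimization runs once on the winning correspondence.
Correspondences are strictly monotonic by construction (global DP).

## Template libraries

*DB-Het.* Assemblies with resolution worse than 4.0 Å are dropped
(assemblies without a recorded resolution are kept). Every ordered pair of
chains with different sequences and a non-empty interface is a candidate;
pair-level redundancy removal keeps the first representative of any group
whose *both* chains exceed 70% identity to a kept entry, testing the direct
and the swapped part pairing, so that (B,A) collapses onto (A,B) but novel
pairings of common chains survive.

*DB-Mo/Ho.* Single chains are monomers; multi-chain assemblies whose chains
share one sequence are homo-oligomers (one entry each, exposing the chain
pair with the largest interface); mixed assemblies belong in DB-Het. Greedy
retention in input order enforces the 70% mutual identity cap at the
source-structure level. Monomer chains are decomposed into contiguous
domains by recursively cutting at the position minimizing inter-segment CA
contacts (< 8 Å) normalized by the product of segment lengths, subject to a
minimum segment length of 30 residues and a density threshold of 0.04
contacts per residue pair; chains that do not split are stored as single-part
entries that count toward redundancy bookkeeping but cannot template a dimer.

*Interfaces.* Residue i of one part is an interface residue iff any of its
CA/CB atoms lies within 8 Å of any CA/CB atom of the other part. A library
persists as one PDB per entry plus a JSON index (ids, kinds, sequences,
interface lists, resolutions); save → load → save is byte-identical, with
coordinates at the PDB's three decimals.

## Template search

Structure-based search runs the structural aligner for both subunits against
both part orderings of every DB-Het entry. Sequence-based search ranks all
DB-Mo/Ho parts per subunit (top 200 kept) and pairs different parts of the
same entry, verified structurally. Retention thresholds: subunit TM > 0.4
(both), interface TM ≥ 0.4. The interface TM places each subunit onto its
part with the full-alignment Kabsch fit (exactly the model-building
transform, hence input-frame invariance), restricts the correspondences to
template-interface residues, and scores the pooled pairs under those
placements with d0 of the pool size and no further refit — a further
maximizing fit was observed to lock onto one subunit's block and hide
interface-region mismatches, flooring the score near 0.5. The same 0.4
interface threshold applies to two-domain monomer templates, whose
inter-domain interface plays the role of the oligomer interface. A resource
guard truncates hit lists beyond 2000 by template score.

## Model building, filtering, ranking

Each hit produces a model by Kabsch-fitting each subunit's aligned CA set
onto its part; internal subunit geometry is exactly preserved (pairwise CA
distances match to 1e-9 Å in tests). Defaults for the physical filters —
all configurable, chosen as permissive sanity bounds rather than tuned
values: clash distance 3.0 Å with at most 0.1 clashes per residue of the
shorter chain; at least 5 inter-chain CA contacts at 8 Å (clash pairs
excluded); at least 300 Å² buried area, computed by Shrake–Rupley on
CA-centered spheres of radius 3.4 Å with a 1.4 Å probe and 960 points per
sphere (the coarse residue-sphere model matches the two-sphere closed form
to 2%).

Ranking uses template score = TM1 + TM2 + 2·TM_interface; the interface term
is double-weighted as the dimer-specific signal (weights are config keys).
Redundancy removal walks models in score order and accepts a model only if
its complex TM-score to every accepted model is ≤ 0.8; the complex TM
concatenates the chains (A then B) with an identity correspondence and one
joint TM optimization normalized by total length. Ties in the final ranking
break by interface TM then source id, making runs byte-reproducible; at most
50 models are delivered. Externally docked poses (PDB files plus an optional
score table) can be merged below the template-based models; no docking
engine is bundled.

## CAPRI evaluation

Chain pairing between model and reference is by best global sequence
identity (swapped if that pairing scores higher). fnat counts reference
inter-chain CA contacts at 8 Å reproduced by the model; the classical
all-atom definition uses 5 Å, raised here to compensate for the CA-only
representation (both cutoffs configurable). L-RMSD superposes on the longer
reference chain and measures the other without refitting; I-RMSD jointly
fits the reference interface residues (CA within 10 Å across chains).
Classes: high — fnat ≥ 0.5 and (L-RMSD ≤ 1 or I-RMSD ≤ 1); medium — fnat ≥
0.3 and (L-RMSD ≤ 5 or I-RMSD ≤ 2); acceptable — fnat ≥ 0.1 and (L-RMSD ≤ 10
or I-RMSD ≤ 4); else incorrect. The tiers are nested, so improving any
metric never lowers the class.

## Synthetic data: what it emulates, what it does not

Generators produce CA/CB-only idealizations: α-helices (rise 1.5 Å, twist
100°, radius 2.3 Å), pleated strands, persistent random coils, and compact
"bundles" of randomly oriented helical segments standing in for globular
folds. `make_dimer` centers both chains, pre-orients their principal axes,
rotates the second chain by the requested angle about the packing axis,
translates it so the minimal inter-chain CA–CA distance equals the requested
gap (4.2–4.5 Å for natives, matching closest-approach distances in real
interfaces), and applies a small deterministic tilt search (±8°) that
maximizes contact count — without it, random convex shapes touch at a point
and bury unrealistically little area. All generators own a seeded RNG and
are bit-reproducible.

The planted-template benchmark hides a 0.3 Å-perturbed copy of the target
dimer under a scrambled id among decoy dimers whose chains are
rejection-sampled to TM < 0.4 against both target subunits (verified, not
assumed). Passing it demonstrates that search thresholds, assembly,
filtering and ranking interlock correctly — it does not demonstrate
performance on real structures, where templates are partial, alignments
gapped, interfaces chemically heterogeneous, and decoys can be homologous.
No Ramachandran validity, side chains, or sequence–structure consistency is
emulated.

Study conditions used by the tests and the acceptance script: 40-residue
subunits, 20 decoys + 1 plant per trial, 20 trials; TM-oracle fixtures of
30–60 residues at 0.3–0.6 Å noise; 30-model redundancy sets; 50
superposition instances of 10 points.

## Numerical choices and degenerate inputs

- Kabsch: collinearity detected by rank of the centered coordinates
  (tolerance 1e-10); reflections excluded via the sign of det(V·Uᵀ).
- TM iteration: selection sets, not scores, define convergence; cutoffs
  never drop below 3 Å (or d0 when d0 < 3 Å).
- Structural DP: constant gap penalty 0.6; traceback prefers the diagonal on
  ties, keeping co-optimal paths deterministic.
- Interface extraction at cutoff ≤ 0 returns empty sets; contacts use strict
  inequality.
- fnat is an error (not 0) when the reference has no inter-chain contacts;
  I-RMSD is an error when the reference interface is empty or fewer than 3
  interface residues are mapped.
- File I/O: first model only; altloc '' or 'A'; waters/heteroatoms dropped;
  chains under 10 residues treated as peptide ligands and dropped at read
  time; residue numbers preserved verbatim while all internal indexing is
  0-based positional.
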