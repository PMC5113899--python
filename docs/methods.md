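# Methods

This note documents the models, parameters and numerical choices behind
`tmbundle`, in the spirit of a methods appendix: what each component
assumes, where the design was genuinely open, and what the synthetic tests
do and do not demonstrate.

## Contact normalization

Coevolution predictors emit ranked residue-pair lists whose "reliability"
scores live on method-specific scales (EVfold's, for instance, decays
almost exponentially).  To compare and combine predictions, each list is
transformed by rank:

    e = exp(−r² · 0.01 / L)

with `r` the 1-based rank and `L` the protein length.  The count of pairs
with `e > exp(−1)` is `10·√L`, so the usable-contact budget scales with
the square root of protein size.  Ranks are assigned by descending raw
score with deterministic `(i, j)` lexicographic tie-breaks; rank is
1-based, so the top pair scores just under 1 and the transform stays
strictly monotone.

**Combination rule.**  No canonical rule exists for merging predictors'
lists; we sum `e` over contributing sets (a missing pair contributes 0),
re-rank, and re-transform so the consensus lives on the same (0, 1] scale.
Summation on the `e` scale is the minimal choice consistent with the
transform's purpose — equalizing score distributions across methods.

## Contact-map stripe parsing

Contacts between two packed helices form stripes: `j − i ≈ c` for parallel
packing, `i + j ≈ c` for antiparallel.  For each segment pair the block of
contacts is fitted with both stripe models at fixed slopes ±1 and a
triangular residual kernel of half-width `w = 4` residues:

    strength = max_c Σ e · max(0, 1 − |residual(c)| / w)

The objective is piecewise linear in the intercept `c`, so the optimum is
attained at a data offset; ties take the smallest intercept.  Fixed slopes
(rather than free regression) keep the parallel/antiparallel discrimination
well-posed on sparse blocks.  A block needs at least 3 supporting contacts
for a non-"none" label (two points fit any line); exact strength ties
default to antiparallel, the overwhelmingly common case in TM bundles.

**Boundary optimization.**  Declared TM segments are often a few residues
short or long; each segment's start and end may shift by up to `max_shift`
residues (default 5) to maximize the total winning-stripe strength over
all segment pairs, subject to segments staying ordered, non-empty and
within the chain.  Because non-adjacent helix pairs (e.g. a 1–4 packing)
couple distant segments' shifts, a simple chain recursion cannot be exact;
the optimizer instead runs max-sum variable elimination over the
segment-interaction graph, which is exact for this objective.  Strengths
are quantized to integer units of 1e−9 and the tie-break — smallest total
absolute shift, then lexicographically smallest shift vector — is encoded
as exact integer tuple components, so the optimum is fully deterministic
and provably equal to exhaustive enumeration (asserted on random instances
in the test suite).  Cost grows with the clique sizes of the interaction
graph; for realistic bundles (≤ ~14 helices, sparse packing) it is
well under a second at `max_shift ≤ 2` and a few seconds at 5.

## Model scoring

Models are judged at the Cα level.  To distinguish the two faces of a
helix, each residue gets a pseudo-centroid placed 2 Å beyond the Cα along
the negative bisector of the adjacent virtual bonds — the outward,
Cβ-like direction (verified on ideal helices: centroids lie farther from
the helix axis than their Cα).  Terminal residues copy their neighbour's
offset; a locally straight chain leaves the centroid on the Cα.

A predicted pair `(i, j)` contributes `e · q(d)` with

    q(d) = exp(−(d − d0)² / s²),   d0 = 5 Å, s = 5 Å

peaked at the expected minimum centroid separation in native structures:
separations beyond 10 Å score under 0.37, a coincident pair also scores
0.37 (sub-ideal separations are mildly penalized by the symmetric
Gaussian, taken literally), and beyond 15 Å the score is essentially zero.
The model score sums the top `N = 100` pairs with sequence separation ≥ 8
(two helix turns, to stop local contacts dominating).  Rankings are
insensitive to factor-of-two changes in `s` and `N` (asserted on
fixtures).  The reliability entering the product is always the
rank-transformed `e`, not the method-native probability, for the same
distribution-equalizing reason as above.

## Bundle axis, axial RoG and handedness

Each TM segment gets two 4-residue capping zones: the two terminal
residues plus the two beyond.  An `extend` parameter (0–10) slides the two
outward residues further out for use when topology predictions are
variable; the extension saturates so no cap residue sits more than 10
positions outside the segment.  The trigger for extension is left to the
user rather than auto-detected.

Cap midpoints define one axis candidate per helix (N-cap → C-cap).
Starting from the most widely separated pair, candidates are folded in by
decreasing separation as a running mean of midpoints and directions; a
candidate whose direction opposes the running mean is flipped first, so
antiparallel helices reinforce the axis instead of cancelling it.  The
axial radius of gyration is computed about the infinite line through the
final mean point along the final mean direction (a single line keeps the
measure well-defined and rigid-motion invariant), with one shared axis for
all three weighting schemes:

| scheme    | TM residues | cap residues | rest |
|-----------|------------:|-------------:|-----:|
| `tm_only` | 1           | 0            | 0    |
| `tm_caps` | 1           | 0.5          | 0    |
| `whole`   | 2           | 1            | 0.5  |

(a residue inside both a segment and a cap counts as TM).  As operational
guidance, RoG > 15 Å almost always indicates a stray helix and RoG > 12 Å
deserves inspection; these thresholds vary slightly with protein size.

**Handedness.**  Distance constraints cannot distinguish a bundle from its
mirror image, so chirality is reported separately: helix midpoints are
projected onto the plane normal to the bundle axis and the signed area of
the cyclic polygon they trace in sequence order gives the sense (+1
clockwise viewed from the tip of the canonical axis, −1 anticlockwise,
0 degenerate).  The axis sign is canonicalized to the first helix's N→C
direction so the result is independent of cap accumulation order and of
rigid motions; mirroring always flips it.

## Weighted superposition and RMSD suite

Plain RMSD is skewed by a few deviant positions (typically long loops).
Residues are weighted by the similarity of their structural environments;
as the environment descriptor we use the internal distance profile:

    Δ_i = mean_j | d_a(i, j) − d_b(i, j) |,    w_i = exp(−Δ_i / σ),  σ = 4 Å

This is a deliberately simple, fully specified context measure — it is a
substitute for iterated structure-alignment environment scores, with the
same contract (continuous, context-derived, in [0, 1]); since all models
share one sequence there is no alignment problem.  The superposition
minimizes `Σ w_i ‖a_i − (R b_i + t)‖²` by weighted Kabsch (SVD with
determinant correction; reflections excluded, so enantiomers retain a
positive residual), cross-checked in the tests against an independent
reference implementation.  Besides the environment-weighted RMSD, the
three RoG weighting schemes above give three more wRMSDs, each from its
own superposition.

## Fold-space projection

Pairwise wRMSD values are treated as distances and embedded into 2 or 3
dimensions for visual clustering.  wRMSDs from different superpositions
need not satisfy the triangle inequality, so the matrix is first repaired
by replacing every violating entry with its tightest path bound
(all-pairs shortest paths; entries are only ever tightened).  The repaired
matrix is embedded exactly in `n−1` dimensions by classical scaling
(pairwise distances always admit a consistent Euclidean metric in `n−1`
dimensions), then the dimensionality is halved stage by stage down to the
target, each stage refined by weighted stress majorization (SMACOF) with
pair weights `min(1, scale/δ)`, `scale = 10` Å — distances below 10 Å
count fully and weaker similarities are down-weighted by their reciprocal.
Convergence: relative stress change < 1e−6, ≤ 500 iterations per stage;
the seed controls only an infinitesimal symmetry-breaking jitter, so runs
are reproducible.  The reported stress is `Σ w(δ−d)²/Σ w`.

## Top-slice selection

With model score `y` against axial RoG `x`, good models lie upper-left
(high score, compact).  A slice `y = g·x + c` with gradient `g = 10` is
lowered (`c` chosen) until at most `max_n = 20` models lie above it —
equivalent to taking the top 20 by margin `y − g·x`, with boundary ties
broken by higher score, then lower RoG, then model id.  One slice is taken
per contact set; models occurring in at least `min_count = 3` slices form
the consensus pool, ordered by recurrence then mean margin.  A
`balance_pool` helper evens out per-construction-method counts by keeping
each method's most-recurrent models.  The pipeline deliberately stops at
the ranked pool plus its score table — synthesizing the pool into a single
structure is a job for an external modelling engine.

## Synthetic data

The generator builds idealized bundles: textbook α-helix geometry (rise
1.5 Å/residue, twist 100°, Cα radius 2.3 Å), helices at equal angles on a
circle (default radius 8 Å, four helices of 20 residues), alternating
up/down, joined by loops laid on an arc-length-resampled path with ~3.8 Å
spacing.  Oracle contacts list pairs with centroid separation within a
cutoff (default 8 Å) and sequence separation ≥ 5, scored `1/(1+(d/c)²)`;
centroid (not Cα) distances are used so the true structure can attain the
scoring maximum.  `rank_noise` swaps a seeded fraction of adjacent rank
pairs to emulate imperfect predictor rankings.  Decoy families: mirror
images, stray helices (radial translation), swapped-helix re-threadings
(reversing the incoming helix when slot directions oppose), and Gaussian
coordinate noise.  All generators are pure functions of (spec, seed).

What the synthetic fixtures do **not** emulate: helix kinks and tilts,
re-entrant and half helices, loop structure, sequence-dependent contact
densities, and predictor-specific error correlations.  Passing tests
demonstrate the internal consistency and discriminative behaviour of the
measures under idealized geometry, not performance on real predictor
output.

## Problem sizes in the test suite

Tests run on 4-helix, ~100-residue bundles, ensembles of ≤ 20 models, and
boundary-optimizer instances of 3 helices with shifts ≤ 2 (where exhaustive
enumeration is feasible as an oracle); these sizes exercise every code
path while keeping the full suite under a couple of minutes.

## Known limitations

- The stripe strength functional is a declared substitute for an
  unspecified regression criterion; alternative functionals may reorder
  marginal parallel/antiparallel calls.
- The environment weighting is a simple distance-profile measure, not a
  full structure-alignment environment score.
- Cap-based axes tilt slightly on very short or strongly phased helices
  (cap midpoints sit off the true helix axis); axial RoG inherits a small
  bias there.
- The handedness sign is undefined (0) for collinear helix arrangements
  and relies on the first helix crossing the membrane roughly along the
  bundle axis.
- PDB input is restricted to single-chain, no-insertion-code Cα traces by
  design; renumber or split upstream if needed.
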