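# Methods

This note documents the models, parameters and numerical choices behind
`distfold`, and what its synthetic benchmarks do and do not demonstrate.

## Scope and data model

The toolkit operates on reduced protein representations: one CA coordinate
per residue, an optional CB (never for glycine), and 0-based contiguous
residue indexing. Models and natives are assumed to share the target
sequence, so all comparisons are index-aligned; no sequence-dependent
structure alignment is performed anywhere. Distance maps are real-valued
symmetric L×L matrices with a validity mask and optional per-pair
confidence in [0, 1] — binned distance histograms are deliberately out of
scope, with the real-valued map as the single interchange format.

## Folding from a distance map

### Restraints

Every masked-in pair (i, j) with predicted distance d ≤ `d_max` (default
16 Å — a typical validity horizon for predicted distances; configurable)
and confidence ≥ `min_confidence` becomes a flat-bottom restraint
[d − w, d + w] with half-width w = 1.0 Å and weight equal to the pair's
confidence (1 when absent). Sequential CA–CA restraints [3.7, 3.9] Å with
weight 10 are always added: chain connectivity must dominate map-derived
terms, and the 10× factor keeps it dominant without making the problem
stiff. The half-width is chosen so that exact maps are strictly feasible
(zero energy at the truth).

### Optimization

1. **Completion + embedding.** The restraint graph (edge lengths =
   restraint midpoints) is completed by all-pairs shortest paths and
   embedded in 3D by classical multidimensional scaling. Shortest-path
   completion overestimates missing distances only mildly for chain-like
   graphs, so the embedding already has the right global shape. A
   disconnected graph is a hard error naming the disconnected segments.
2. **Flat-bottom minimization.** L-BFGS with the analytic gradient of
   E = Σ w·max(0, l−d, d−u)², run from the MDS embedding and from
   `n_restarts` − 1 jittered copies (Gaussian σ = 0.5 Å from the seeded
   generator). The lowest-energy restart wins.
3. **Gauss-Newton centering.** The flat-bottom energy is exactly zero on a
   whole manifold (any structure inside every window), and near-planar
   chains admit flex modes whose distance error grows only quadratically
   with amplitude — a first-order minimizer stalls there with ~0.7 Å of
   residual error. A weighted least-squares pass on the residuals
   d − midpoint (trust-region Gauss-Newton) converges quadratically and
   selects, within the feasible region, the structure closest to the
   predicted distances. The refined solution is kept only if it does not
   worsen the flat-bottom energy, so the optimizer contract (final energy
   ≤ initialization energy) is preserved unconditionally.

Everything is deterministic given the seed; model seeds used by the
pipeline are `seed + i`.

### Chirality

A distance map is invariant under reflection, so folding returns both
enantiomers and resolution is an explicit separate step: against a
reference structure (higher TM-score, or lower RMSD below the TM-score
length limit), or from secondary structure — helical segments (runs of
'H' ≥ 6) of the correct enantiomer have CA pseudo-dihedral medians near
+50° (IUPAC sign convention). With no hint the primary model is returned
and the ambiguity is logged; the pipeline keeps a model pool
self-consistent by hinting all folds with the first one.

## Map agreement and distance ranking

The similarity between a predicted map and a model is the (confidence-
weighted) mean over scorable pairs of the bounded kernel
1/(1 + ((d_model − d_pred)/w)²), w = 2 Å. Scorable = masked-in, predicted
distance ≤ 16 Å, sequence separation ≥ the configured minimum. The kernel
reaches 1 exactly when the model reproduces every scorable distance; its
bounded tails keep single outlier pairs from dominating, which a quadratic
loss would not. The 2 Å width matches the scale at which sub-Å modeling
error should still score near 1. This functional form is this package's
choice; only the *principle* of ranking by map agreement is inherited
from the systems that inspired it.

## Consensus ranking

A model's consensus score is its mean TM-score against every other model
in the pool. Pools whose plurality of models share a fold reward members
of that dominant cluster; isolated wrong folds score low. The pairwise
matrix is computed once for i < j and symmetrized (index-aligned TM on
equal lengths is symmetric up to search noise). External single-model
scores (e.g. an energy function) can be loaded as additional columns, and
arbitrary columns combined by weighted mean rank — ties break by the
first listed column, then model id, for determinism.

## TM-score and GDT_TS

Both metrics maximize over rigid superpositions seeded from contiguous
fragments: fit the fragment by least squares (Kabsch, proper rotations
only), then iterate "superpose on the residues currently within the
cutoff" to a fixed point, scoring *every* pose along the trajectory (the
best pose is often not the converged one). TM-score uses cutoffs
{max(4.5, d₀), 8} Å and d₀ = 1.24·(L−15)^⅓ − 1.8 floored at 0.5 Å
(L ≥ 16 enforced; the floor keeps d₀ positive near the limit); GDT_TS
refines at each of {1, 2, 4, 8} Å and every pose is a candidate for every
cutoff. Chains shorter than 33 residues always get the exhaustive seed
enumeration (every fragment of every length ≥ 4): it is cheap there, and
GDT's discreteness at small L makes a single missed pose cost whole
points. Longer chains use fragment lengths {L, L/2, L/4, 4} with
half-overlapping starts. Acceptance is defined as oracle equivalence on
small instances, not bit-compatibility with the original programs.

## Z-score aggregation

Raw score = Σ weight·metric with default weights gdt_ts = 1, qcs = 1,
molprobity = 0.1. QCS and MolProbity are always externally supplied
columns — this package never computes them — and whether MolProbity
enters negated (lower = better) is the caller's decision via the sign of
the supplied column. Standardization uses the population SD across
predictors per target; a zero-SD target logs a warning and contributes
z = 0 for everyone. Contributions with z < −2 are discarded (or clipped,
by flag); missing predictions contribute 0. Note that with n predictors
the extreme z is bounded by ±(n−1)/√n, so the discard rule can only
trigger for n ≥ 6.

## Domain splitting

Coverage is the union of hit intervals with E ≤ 10⁻³ (the ">40 residues"
gap threshold is the established splitting rule; the significance cutoff
is this package's default and configurable). Maximal uncovered runs
strictly longer than 40 residues become FM segments; shorter gaps are
absorbed into flanking TBM. A TBM island shorter than `min_tbm_len`
(default 40) that touches an FM segment is too small to be its own
modeling unit and merges into that FM neighbor (left preferred). These
choices keep the output a partition with alternating labels, idempotent
under re-splitting, and monotone: raising the E-value cutoff never
converts a TBM residue to FM.

## Neff

Identity between two aligned rows is computed over their mutually
non-gapped query columns (query = row 0; columns gapped in the query are
dropped, as are lowercase A3M insert states on input). Weight = 1/(number
of rows ≥ 80 % identical, self included); Neff = Σ weights, in [1, N].
The 0.8 threshold is the prevailing convention (0.62 is exposed as an
alternative); no √L or length normalization is applied, and the natural
log is provided separately as the usual plotting axis.

## Synthetic study conditions

The fixture generator defines the conditions every benchmark runs on:

- **Topologies**: ideal helix (rise 1.5 Å, 100°/residue, radius derived
  as √(3.8² − 1.5²)/(2 sin 50°) ≈ 2.279 Å so consecutive CA spacing is
  exactly the 3.8 Å virtual bond), planar zigzag, self-avoiding random
  coil (bond angles 85–145°), and 2–3-helix bundles with equal-chord arc
  linkers at 9.8 Å axis separation. All chains are self-avoiding
  (non-sequential pairs > 3.5 Å) and deterministic per seed.
- **Noisy maps**: one Gaussian draw per unordered pair (mirrored, so the
  per-pair error is exactly N(0, σ²)), a configurable fraction of
  long-range pairs corrupted to uniform [4, 20] Å, confidence
  exp(−err²/8) truncated to [0.05, 1], distances floored at 2 Å.
- **Decoys**: native + i.i.d. coordinate noise, re-idealized to exact
  3.8 Å spacing by a sequential direction-preserving pass. The pass turns
  positional noise into cumulative directional drift, so a decoy's global
  deviation grows along the chain and is larger than its nominal σ —
  labels order decoys by quality but are not calibrated RMSD values.
- **Benchmark sizes**: folding recovery and ranking at L = 40 (20-seed
  replicates), metric-oracle suites at L = 18, contact precision at
  L = 60. These desk-scale sizes exercise every code path in minutes.

What passing these benchmarks shows: the folding stage inverts its own
forward model (map → structure) robustly, rankers track true quality on
graded pools, and the metrics match exhaustive-search oracles. What it
does not show: performance on real predicted maps, whose errors are
spatially correlated and systematically biased in ways the i.i.d. noise
model does not emulate, nor the behavior of full-atom models.

## Known limitations

- CA/CB only; no side chains, no secondary-structure prediction, no
  template-based modeling branch, no domain-model joining.
- Index-aligned metrics only: models must share the target's length.
- TM-score requires L ≥ 16 (d₀ formula); use RMSD below that.
- The flat-bottom potential and its optimizer are a documented stand-in
  for simulated-annealing distance-geometry engines; they are adequate at
  desk scale but untested at L ≫ 100.
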