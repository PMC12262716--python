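# Methods

This note documents the models and procedures implemented in
`consentropy`, the parameter choices that matter, what the synthetic data
generator does and does not emulate, and the numerical decisions taken
where the design was genuinely open.

## Data model

A *labeling* is one clustering of a spatial sample: unique observation ids,
2-D coordinates, and a categorical label per observation, with provenance
(`method_id`, `config_id`, `sample_id`). Labels are recoded to dense
integers `0..K-1` on ingest (codes assigned in sorted order of the original
label strings, so recoding is deterministic); the original strings are kept
for output. A *collection* stacks M labelings of the same sample into an
N×M label matrix on the lexicographically sorted **intersection** of their
observation ids. Intersection semantics were chosen because the consensus
algorithms need a complete matrix and, in practice, labelings of one sample
differ only when a method discards observations; dropped ids are recorded.
Coordinates must agree across labelings within 1e-6 per axis — a larger
discrepancy indicates the files do not describe the same sample and is an
error, not something to average over.

## Entropy metrics

All entropies are Shannon entropies of empirical class frequencies with the
natural logarithm (nats), `0 log 0 = 0`. Bounds quoted in code and tests
are `log m` for `m` classes.

**Smoothness entropy (SE).** For each observation, the entropy of the label
multiset {own label} ∪ {labels of its k nearest spatial neighbors}
(Euclidean k-NN, default k = 6); the scalar SE is the mean over
observations. No distance cutoff is applied by default; when one is set and
an observation retains no neighbors, it contributes entropy 0 (a lone point
has no local disagreement). Lower SE = spatially smoother labeling; SE is
invariant to relabeling.

**k-NN graphs.** Neighbor lists are computed from explicit distance
matrices (chunked for memory) with ties broken by ascending observation
position. The tie-break matters on lattices, where equidistant neighbors
are common: it makes every graph, and hence every SE/border value,
bit-reproducible. Distance cutoffs prune *after* the k-selection.

**Border spots.** An observation is a border spot if any retained neighbor
(default k = 4, distance cutoff 1.5 — suited to unit-spaced lattices, where
it keeps the rook neighbors and drops nothing closer) carries a different
label. An observation with no retained neighbors is not a border spot.

**Cross-method entropy (CME).** Cluster codes are arbitrary per method, so
columns are first aligned: for a reference column r, each other column's
codes are bijectively remapped to maximize total overlap with r (Hungarian
assignment on the confusion matrix, padded to square; source classes
matched to padding receive fresh codes beyond the reference alphabet). The
per-observation entropy across the M aligned labels is computed, and the
final CME is the mean over all M choices of reference — the reference
choice is arbitrary and averaging removes it. CME is reported unnormalized;
a normalized variant (divided by the log of the largest aligned alphabet)
is available. CME is zero at an observation iff the aligned columns agree
there under every reference.

**Pairwise agreement.** ARI/NMI matrices delegate to scikit-learn. The ARI
degenerate case (expected index equals maximum index, e.g. single-cluster
columns) returns 1 if the two columns are identical as set partitions and 0
otherwise. The test suite checks the full matrix against a hand-written
pair-counting oracle.

## Consensus algorithms

All three operate on the N×M matrix of dense label codes and are
permutation-equivariant in each column's codes. Identical seeds give
bit-identical results.

**K-modes.** Rows are partitioned into K groups minimizing the total
Hamming distance to each group's column-wise mode vector. Initialization
samples K distinct rows; mode ties resolve to the smallest code; an empty
cluster is re-seeded from the row farthest from its current mode. The
objective is non-increasing per iteration; the best of `n_starts` (default
10) restarts is returned. Verified against exhaustive enumeration of all
assignments on small instances.

**Latent class analysis.** The categorical mixture
`P(x_i) = Σ_k π_k Π_m θ_{mk, x_im}` fitted by EM with a Dirichlet
pseudocount (default 0.1) on the conditional updates. The monotone
objective reported in `objective_trace_` is the penalized log-posterior
(the observed-data log-likelihood alone is not guaranteed monotone under
MAP updates); `log_likelihood_` reports the final observed-data value, and
restarts (default 10, random Dirichlet responsibilities) are ranked by the
penalized objective. Consensus labels are MAP latent classes. One
degenerate case is short-circuited: with a single base clustering the
mixture is unidentifiable from one categorical observation (any
parameterization reproducing the marginal is optimal, and the smoothed
objective prefers the uninformative one), so M = 1 with K ≥ the alphabet
size returns the column unchanged — which is the only sensible consensus
of one labeling.

**Weighted Jensen–Shannon consensus.** Objective

    min_{S, ω}  Σ_m ω_m JSD(S ‖ S^(m)) + λ Σ_m ω_m log ω_m,   Σ ω_m = 1, ω ≥ 0

with S ∈ [0,1]^{N×N} the consensus co-association matrix and S^(m) the
binary co-association matrix of column m. Numerical choices:

- `JSD(S‖S^(m))` is the **mean** entrywise Bernoulli JSD over off-diagonal
  pairs. Defining it as a sum would make the divergence scale as N², so any
  fixed λ would degenerate to a one-hot ω on large samples; the mean keeps
  each divergence in [0, ln 2] and gives λ a sample-size-free meaning.
  Diagonal entries are fixed at 1 and excluded (self-pairs carry no
  information).
- Optimization is exact alternating minimization. With ω fixed, each entry
  s_ij independently minimizes `a·JSD(s,1) + (1−a)·JSD(s,0)` where
  `a = Σ_m ω_m s^(m)_ij` is the ω-weighted vote — a 1-D convex problem
  solved by bounded scalar minimization once per distinct vote value (there
  are at most 2^M, in practice far fewer). With S fixed, stationarity of
  the entropy-regularized Lagrangian gives the closed form
  `ω_m ∝ exp(−D_m/λ)`. Both steps solve their subproblem exactly, so the
  objective trace is non-increasing; the tests verify the converged
  objective against an independent L-BFGS-B minimization of the full
  objective.
- λ defaults to 0.1: with mean-scaled divergences this downweights clearly
  discordant labelings without silencing them; λ → ∞ recovers uniform
  weights. S is initialized at the unweighted co-association average, ω at
  uniform; convergence when the objective change drops below 1e-8.
- The converged S is thresholded at 0.01 (edges below are dropped) and
  partitioned with Leiden modularity community detection
  (RBConfigurationVertexPartition, seeded). When a target cluster count K
  is requested, the resolution is binary-searched assuming the cluster
  count is non-decreasing in the resolution; if the exact count is
  unreachable (the count jumps past it), the nearest count is returned with
  a flag, preferring fewer clusters on ties.
- Dense N×N storage caps N at 20 000 by default; beyond that the method
  errors explicitly rather than thrashing.

## Selection rules

- *Imbalance filter*: drop columns whose modal class holds strictly more
  than a threshold (default 0.9) of observations — such labelings carry
  almost no partition information and poison mode/mixture estimates. The
  boundary is strict: exactly 90% is kept.
- *Concordance block*: rows of the pairwise-ARI matrix (diagonal included,
  as plain row vectors) are hierarchically clustered with Euclidean
  distance and complete linkage, the tree is cut into `n_groups` (default
  2), and the block with the highest mean within-group off-diagonal ARI
  among groups of at least `min_block_size` (default 3 — a consensus of
  fewer than 3 is degenerate) is kept. The mean-internal-ARI criterion
  formalizes the visual "pick the concordant block" step when a cut yields
  several groups.
- *Smoothest-n with per-algorithm dedup*: keep the lowest-SE labeling per
  `method_id` first (so one method run under many configurations cannot
  dominate), then the n lowest-SE survivors; ties break on provenance
  lexicographic order. If fewer than n survive, all survivors are kept with
  a warning rather than an error — the caller asked for diversity and gets
  all of it.

## Leave-one-out validation and granularity sweep

With no trustworthy ground truth, each base clustering is scored against a
consensus of its peers: for column c, a consensus (default LCA) is built
from the `n_base` = 6 smoothest deduplicated remaining columns, and
ARI(c, consensus) is reported. Coherent methods score near 1; a labeling
unrelated to the ensemble scores near 0.

The sweep computes mean CME over a grid of (cluster count k) × (n smoothest
methods), where each k-slice contains only base clusterings with exactly k
classes. Cells with fewer than n available columns are marked infeasible
(NaN) instead of failing, keeping grids rectangular; n = 1 cells are 0 by
definition (one labeling cannot disagree with itself) and flagged
`degenerate-n1` so they are not mistaken for genuine agreement. The argmin
over k of a column is the granularity the ensemble supports best.

## Synthetic data

The generator emulates *label outputs* of disagreeing SAC methods, not
expression data or the methods themselves. Tissues are unit-spaced square
lattices with horizontally layered bands (cortex-like) or rectangular block
tilings; every domain is connected on the 4-neighbor lattice. Noise is
applied to the ground truth in a fixed order — domain merge/split
(granularity mismatch; splits at the coordinate median along the domain's
longer axis), boundary jitter (observations within r lattice steps of a
boundary, measured by BFS on the 4-neighbor graph, flip to the adjacent
domain with probability p_b), iid label flips (to a uniformly random other
label), then optional label permutation (codes are arbitrary per method).
All generators are pure functions of their seeds.

Default study conditions, chosen once: 24×20 lattice with 4 layered
domains; 8 base clusterings with flip rate 0.1, jitter probability 0.3
within radius 1, permuted labels. A 10% flip rate leaves individual
labelings clearly imperfect (single-method ARI ≈ 0.5 against the truth
under the full noise model) while keeping the ensemble informative, which
is the regime where consensus is interesting; the granularity helper
derives wrong-k labelings by rotating which domains are merged or split
across methods, mirroring how real methods forced to the wrong granularity
resolve it differently.

What passing tests on this generator do **not** show: real SAC methods
produce spatially correlated, method-specific error structure (shared
preprocessing, similar graph constructions) rather than independent noise;
real tissues have curved boundaries, holes and hex/irregular coordinate
layouts; and real method disagreement is often systematic (two methods
consistently merging the same pair of domains), which weakens both the
independence assumption behind LCA and the localization of CME at
boundaries. Results on the generator demonstrate correctness of the
machinery, not performance on tissue.

Problem sizes throughout the test-bench (N in the hundreds, M ≤ 9) were
chosen so the full suite and the acceptance workflow run in seconds while
every statistical check operates far from its decision boundary.

## Known limitations

- The weighted consensus is quadratic in N (dense co-association matrices);
  use K-modes or LCA for large samples.
- LCA assumes base clusterings are conditionally independent given the
  consensus class; heavily correlated method families violate this and are
  better thinned first via the concordance block and per-algorithm dedup.
- The resolution search assumes the Leiden cluster count is non-decreasing
  in the resolution parameter; this holds in practice but is not
  guaranteed, and the search falls back to the nearest achievable count.
- Consensus here uses no spatial information beyond what the base
  clusterings encode; a spatially constrained consensus is an extension
  point, not implemented.
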