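# Methods

## The balanced minimum evolution criterion

For `n` taxa with distance matrix `D = {d_ij}` (symmetric, zero diagonal,
positive off-diagonals), every unrooted binary tree `T` on the taxa
induces a path-length matrix (PLM) `τ`, with `τ_ij` the number of edges
on the unique leaf path between `i` and `j`. The balanced tree length

    ℓ(τ) = Σ_{i≠j} d_ij · 2^(−τ_ij)        (ordered-pair sum)

is, up to scaling, the Pauplin weighting of branch lengths: each pairwise
distance contributes with weight halving at every internal node crossed.
Minimising `ℓ` over all `(2n−5)!!` topologies defines the inference
problem; it is NP-hard, so the package combines exact small-`n` tools
with LP-guided heuristics.

### Objective convention (the factor of two)

The product-form "generalized tree length" of a partial (star-of-
clusters) tree weights each ordered pair by `Π_k (δ(k)−1)^{-1}` over the
internal nodes `k` of its path. Evaluated literally on a *completed*
binary tree this equals `2·ℓ(τ)` (a path of `τ` edges crosses `τ−1`
degree-3 nodes, so the product is `2^{1−τ}`). We fix the ordered-pair
`ℓ(τ)` above as the single canonical scale: `generalized_tree_length`
carries a global factor 1/2 so that the star, every intermediate forest
and the final tree are all reported on one scale, and the value at the
final step equals `bme_length` exactly. Optimality gaps are ratios and
are unaffected by this choice.

On the canonical scale the bookkeeping used by the agglomeration and
beam engines is:

* within-cluster part: `lhat = Σ_clusters Σ_{i<j} d_ij · 2^{−(s_ij−1)}`,
  which grows by exactly `d_pq/2` when clusters `p, q` (reduced distance
  `d_pq`) merge;
* cross-cluster part: `Σ_{p<q} d_pq / (m−1)` over the `m` active
  clusters;
* one-step lookahead (BeamNJ ranking): merging `(p, q)` gives
  `lhat + d_pq/2 + (S − (R_p+R_q)/2)/(m−2)` with `S` the unordered pair
  sum and `R` the row sums of the reduced matrix.

All three are cross-checked in the tests against direct product-form
evaluation at every step of random trajectories; this guards the
exponent conventions (cross-cluster pair weight `2^{−(s_ij−2)}`,
within-cluster `2^{−(s_ij−1)}` before the 1/2 normalisation), which are
easy to get wrong by one power of two.

## The PLM characterisation and the integer formulation

A square integer matrix is the PLM of some UBT iff it satisfies: zero
diagonal, symmetry, entries in `[2, n−1]`; metricity with slack 2
anchored at taxon 1 (`τ_1i + τ_1j ≥ 2 + τ_ij` and rotations); the Kraft
equalities `Σ_{j≠i} 2^{−τ_ij} = 1/2` per row; exactly one of the three
strong four-point cases per leaf triple (the tight pair of sums equal,
the slack one smaller by ≥ 2); and the manifold identity
`Σ_{i≠j} τ_ij 2^{−τ_ij} = 2n − 3`. `validate_plm` reports each family
separately; integer inputs are checked in exact dyadic arithmetic
(powers of two and their short sums are exact doubles), float inputs at
tolerance 1e−9.

The optimisation model uses variables `x_ijℓ ∈ {0,1}` (`i < j`,
`ℓ ∈ L = [2, lmax]`) with one-length-per-pair assignment rows, Kraft
rows, triangle rows, the manifold row, and — to make the integer model
exact — big-M Buneman rows with indicator triples `y` selecting the
four-point case (M = 2n−2). With everything on, integer optima are
exactly PLMs and the optimum solves the inference problem; this is the
small-`n` oracle (`solve_integer`, practical to n ≈ 12). Dropping
integrality yields the relaxations:

* **Lower bound** (`lower_bound`): full `L`, triangle on, Buneman off.
  Used for all optimality gaps. Full `L` is kept because a truncated
  range is a restriction, not a relaxation, and would forfeit the bound
  guarantee. Triangle rows are kept: they tighten the bound, and a
  tighter bound yields *smaller* reported gaps, so this choice never
  flatters a heuristic relative to the triangle-free alternative.
* **Guidance LP** (LPNJ / BeamLPNJ): Buneman off, triangle optional
  (the ±Tri variants), truncated `L`, exponent shift on.

### Numerical choices

* *Truncated path-length range*: `lmax = ⌈log₂(n−1)⌉²`, falling back to
  the full `n−1` whenever that is not an actual reduction (n < 38 or
  so) or `n < 5`. The square of the logarithm always leaves room for a
  balanced topology (diameter ≈ 2·log₂ n).
* *Exponent shift*: multiplying the objective and the dyadic rows by
  `2^lmax` makes their coefficients integers, improving solver scaling
  for truncated `L`; outputs are divided back. Verified to change
  reported values by < 1e−7 relatively.
* *Solver determinism*: continuous guidance solves use HiGHS dual
  simplex single-threaded (`highs-ds`), so the fractional tie structure
  of `τ̃` is reproducible run to run; alternative LP optima could
  legitimately change heuristic choices otherwise. The larger
  lower-bound LPs use the interior-point variant (`highs-ipm`), which
  is ~3× faster there; only the bound's value is consumed, not its tie
  structure.

## Heuristics

**NJ.** Pair selection by the Q-criterion
`argmin (m−2)·d_ij − R_i − R_j`; reduction by plain averaging
`d_vk = (d_pk + d_qk)/2`; final three-way join. Ties (exact float
equality) break lexicographically by index pair — the selection scan is
row-major, which implements this for free.

**LPNJ.** Same reduction, but the merged pair minimises the fractional
path-length estimate `τ̃_pq` from the guidance LP on the current reduced
matrix. Ties within 1e−9 break by smaller reduced distance, then
lexicographically. If the guidance LP were replaced by the exact integer
optimum at every step, the result is provably an optimal tree — the
package ships this variant (`guide="integer"`) and the tests confirm
optimality exhaustively at n ≤ 7.

**Beam search.** Width-`B` beam over merge sequences. BeamNJ ranks each
candidate merge by the exact child tree length (incremental formula
above); BeamLPNJ ranks by the lower estimate
`lhat + LP(D^r) + d_pq/2 − d_pq·2^{−(τ̃_pq−1)}`. The parent term is
recomputed fresh from the parent's own LP at every step rather than
chained through previous increments, avoiding accumulation of
estimate drift (one LP per beam member per step either way, since the
pair scores need `τ̃`). Children reaching the same forest through different
merge orders are deduplicated by a canonical forest signature before
truncation (toggleable, since a literal implementation without
deduplication would fill the beam with duplicates). At `B = 1` BeamNJ
is NJ exactly; BeamLPNJ at `B = 1` is the distance-weighted variant of
LPNJ (`argmin d_pq(1/2 − 2^{−(τ̃_pq−1)})`), which agrees with LPNJ on
pairs at `τ̃ = 2`.

**SPR.** Best-improvement hill climbing over the subtree-prune-regraft
neighborhood, full O(n²)-per-neighbor recomputation of the tree length,
relative improvement threshold 1e−12 against float cycling, ties by
first occurrence in the deterministic enumeration order. Fine up to a
few dozen taxa; the incremental update tables of production SPR
implementations are out of scope, so refined gaps here are comparable
to, but not bit-identical with, those of other SPR codes.

## Synthetic benchmark suites

* **Set C (RDSM)**: symmetric uniform(0,1) start, zero diagonal,
  symmetric Sinkhorn–Knopp sweeps (divide by the geometric mean of row
  sums, re-symmetrise) to row sums 1 ± 1e−8, cap 10⁵ sweeps. The
  initial distribution is a modelling choice (uniform is the simplest
  construction consistent with a symmetric doubly stochastic target);
  other choices would shift mean gaps slightly.
* **Set D (RIM)**: symmetric, off-diagonals i.i.d. uniform on
  {1, …, 10}, zero diagonal.

Both are pure functions of `(n, seed)`; suite seeds derive from a master
seed via `SeedSequence([master, set, n, replicate])`, so a whole
benchmark is reproducible from one integer. These matrices are *not*
tree-like (they emulate the hard, unstructured regime where LP bounds
are loose and heuristics differ most); they do not model estimation
noise from finite sequences, rate heterogeneity, or near-additivity of
real biological distance matrices. Passing benchmarks here demonstrates
optimisation quality relative to the LP bound, not statistical accuracy
of tree recovery — the additive-matrix recovery tests cover that
separately at small scale.

## Optimality-gap protocol and problem sizes

Gap per instance: `100·(ℓ − bound)/bound`. Aggregates pool all `n` of a
set equally (unweighted mean); "best" percentages credit every method
tied within 1e−9 of the per-instance minimum, so columns may sum past
100.

The packaged benchmark grid is `n ∈ {10, 15, …, 50}` with 10 matrices
per size per set (the acceptance script), and a smaller smoke grid
(`n ≤ 35`; BeamLPNJ at `n ≤ 25` with 5 replicates) inside the test
suite. The cost is dominated by the full-`L` lower-bound LP, which
grows steeply with `n` (~10 s at n = 50, ~30 s at n = 60 per instance
with the interior-point solver); the grid caps were chosen so a full
rerun stays in the tens of minutes on one CPU. Mean gaps increase with
`n` on both suites, so pooled means from these grids are slightly
below what a grid extended to n = 60 would give.

## Known limitations

* LP-guided methods solve O(n³)-sized LPs per step and are practical
  only to moderate `n`; BeamLPNJ multiplies that by the beam width.
* The integer oracle is exponential in practice beyond n ≈ 12.
* Branch lengths are not estimated; outputs are topologies with unit
  or omitted branch lengths in Newick.
* The beam's lower-estimate ranking is loose (it is a bound on the best
  completion, not an exact score), which is the known reason BeamLPNJ
  can degrade as `B` grows while BeamNJ improves.
* Rooted trees and non-binary topologies (beyond transient partial
  stars) are out of scope.
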