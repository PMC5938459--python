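# Methods

## The influence model

The taxon influence index treats a Bayesian analysis as a distribution over
tree topologies rather than a single estimate.  For a focal taxon *i*, two
posteriors are compared: the full-data posterior with *i* pruned *a
posteriori* (so both distributions live on the same leaf set), and the
posterior re-inferred from a data matrix with *i* deleted.  The index is
the expectation of a tree distance under the product of the two posteriors,

TII(i) = Σ over pairs (T*, T′) of w(T*) · w(T′) · d(T*, T′),

with weights estimated as sample frequencies of unique post–burn-in
topologies.  The index is zero exactly when every positively weighted
cross-pair is shape-identical, i.e. when dropping the taxon leaves
inference of the remaining relationships unchanged.

Assumptions worth making explicit:

* Posterior samples are treated as exchangeable draws; MCMC
  autocorrelation, convergence and effective sample size are the user's
  responsibility (burn-in is applied, but no diagnostics are run).
* All trees are unrooted.  Rooted input has its degree-2 root suppressed
  on read, because the rearrangement and bipartition distances used here
  are defined on unrooted shapes and MCMC tree samples are conventionally
  unrooted.
* Pruning can make distinct topologies coincide; they are merged and their
  weights summed.  The double sum is algebraically invariant to this
  merge, so the choice is safe (and is tested).

## The SPR-excess distance

RF saturates quickly and branch-score mixes topology with branch lengths,
so the influence distance of choice is the SPR rearrangement distance
scaled by the size of the shared tree: d_SPR / MAST.  Both ingredients are
defined here for binary trees; polytomies are accepted by RF and
branch-score but rejected by SPR/MAST rather than silently resolved.

* **MAST** is computed for unrooted trees as the maximum over shared
  root-leaf choices of the classic rooted-MAST dynamic program.  This is
  exact: any agreement subtree contains some leaf, and rooting both trees
  at that leaf reduces the problem to the rooted case.  A witness leaf set
  is recovered by deterministic traceback (first optimal option in a fixed
  order).  For binary trees on a common leaf set the MAST is always ≥ 3,
  so the excess is never divided by zero.
* **Exact SPR** is NP-hard in general, so exactness is an explicit
  contract: `spr_distance` returns a value plus a flag, `"exact"` for a
  certified minimum from a meet-in-the-middle breadth-first search over
  the SPR graph (canonical bipartition-set deduplication, the smaller
  frontier expanded first, meeting-level bookkeeping that guarantees
  minimality), `"bound"` for a heuristic upper bound.
* **The heuristic bound** is a deterministic greedy descent: repeatedly
  apply the first enumerated SPR move that maximally reduces RF to the
  target.  When no strictly improving move exists the remainder is charged
  at `n − MAST(current, target)` — a valid upper bound, since the trees
  restricted to an agreement subtree are identical and each leaf outside
  it can be regrafted into place with one move.  This also guarantees
  termination.
* **Exactness policy** (`DistanceSpec`): in the default `auto` mode the
  search certifies distances up to `exact_max_distance = 2` and the greedy
  bound covers the rest; `exact` mode runs the unbounded search for trees
  with at most `exact_max_leaves = 9` leaves (the 9-leaf SPR graph has
  135,135 topologies, comfortably enumerable) and raises a capability
  error beyond its limits instead of degrading silently.  The defaults
  trade certification depth for throughput: a TII evaluation touches up to
  |T*|·|T′| tree pairs, and certifying depth 3 on an 11-leaf tree costs
  roughly a second per pair in pure Python, which is disproportionate for
  an index that averages over hundreds of pairs.  Distances within one TII
  computation are memoized by unordered topology pair; memoization cannot
  change results because the distance is a pure function of the pair.

## The resampling estimator

Each iteration draws m = min(|T*|, |T′|) topologies from each posterior
without replacement — successive draws, each proportional to the remaining
weights — and evaluates the double sum on the subsets; the estimate is the
median of 100 iterations (`n_iter`, overridable), with quartiles and
Tukey-fence outlier flags recorded.  Two choices here were genuinely open:

* **Within-replicate weighting.**  The drawn subset's original posterior
  weights are renormalized to 1 (default).  This makes a whole-set draw
  reproduce the exact double sum identically — a sharp, testable anchor —
  and makes the estimator's deviation from the exact value shrink to zero
  as m approaches the set sizes.  Weighting draws uniformly instead is
  available (`weighting="uniform"`) for sensitivity analysis.
* **Sampling discipline.**  "Without replacement according to the
  posterior probabilities" is pinned down as successive conditional draws;
  this is a reproducibility contract (fixed seed ⇒ bit-identical
  replicates), not a claim that other schemes are wrong.

Medians and quartiles use linear interpolation (numpy's default), fixed so
estimates are bit-reproducible across runs and platforms.

## Rankings and their comparison

Taxa are ranked by descending median TII, ties broken lexicographically so
rankings are deterministic.  Rank-biased overlap for conjoint full-depth
lists of n taxa is the extrapolated form

rbo = (1 − p) · Σ_{d=1..n} p^(d−1) · A_d + p^n · A_n,

with A_d the overlap proportion of the top-d prefixes.  The persistence
defaults to p = 0.9 — top-weighted but not myopic (the top ~10 ranks carry
most of the weight) — and is exposed everywhere; no conclusion in the test
suite depends on the default.  Note the p → 1 limit of this extrapolated
form is A_n = 1 for conjoint lists; the familiar "average overlap" limit
belongs to the non-extrapolated variant.

Significance is a one-sided permutation test for *similarity*: the null
distribution is built by uniformly permuting the second ranking, and the
add-one estimator p = (1 + #{null rbo ≥ observed}) / (N + 1) guarantees
p ≥ 1/(N+1); N defaults to 9,999.  Which list is permuted is immaterial to
the statistic (rbo is symmetric).  Under a true null the add-one p-values
are conservative (stochastically ≥ uniform), which is verified by
simulation in the test suite.

Missing-data scores count only `?` as missing — `-` is gap/inapplicable,
not unknown — at a per-taxon proportion of characters; the regression of
median TII on that proportion is ordinary least squares with the two-sided
zero-slope p-value.  Degenerate inputs are explicit errors (zero-variance
predictor) or defined results (constant response ⇒ R² = 0, p = 1).

## The synthetic generator

`random_topology` draws uniformly over labeled unrooted binary shapes by
sequential random edge attachment.  `pseudo_posterior` scatters a chosen
number of distinct topologies 1..max_moves random SPR moves around a
center and gives the center the largest weight of a symmetric Dirichlet
draw, emulating the strongly peaked posteriors the index is designed for.
`planted_influence_suite` builds a full pseudo-posterior plus one
jackknifed pseudo-posterior per taxon whose center is displaced from the
pruned base by a planted number of SPR moves; because a k-move random walk
can realize fewer than k moves of true distance, walks are retried until
the realized SPR separation matches the planted value, so the recorded
truth is a distance, not merely a move count.

The generator emulates topological displacement and posterior peakedness
only.  It does not emulate branch lengths, substitution or morphological
models, MCMC autocorrelation, correlated displacement across taxa, or the
data-driven coupling between a taxon's characters and its influence.
Passing tests therefore show that the estimator recovers *planted
topological* influence under controlled conditions — not that any
particular empirical dataset ranks its taxa correctly.

Default study conditions (chosen once as a realistic desk-scale regime and
used by the acceptance checks): scenarios of 10–16 taxa; displacements
cycling through 0–4 SPR moves; point-mass posteriors for the sharp-signal
case and 4–8 unique trees scattered ≤ 1–2 moves with Dirichlet
concentration 0.7–1.5 for the moderate-dispersion case; 25-tree,
12-taxon posteriors for resampler-consistency measurements; 100 resampling
iterations throughout.

## Known limitations

* Heuristic SPR values are upper bounds; on dispersed posteriors of large
  trees the excess can be overstated, uniformly enough in practice that
  rankings are preserved (this is what the planted-recovery checks
  measure), but individual index values are not certified unless flagged
  exact.
* Posterior weights from short tree samples are noisy frequency estimates;
  the package deliberately offers no smoothing.
* Leave-k-out influence, clade-level influence, and orchestration of the
  external Bayesian re-inferences are out of scope; `write_jackknife_matrices`
  prepares the inputs and the rest of the pipeline consumes the outputs.
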