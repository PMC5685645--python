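# Methods

## Model class and assumptions

`causalmi` learns *ancestral patterns*: mixed graphs over the observed
variables with undirected (−), directed (→) and bidirected (↔) edges and
endpoint marks tail/arrow/circle, where a circle is an undetermined end.
Bidirected edges represent dependence due to an unobserved common cause.
Valid patterns have no directed cycles, no almost-directed cycles (a
directed path between the endpoints of a bidirected edge), and no arrowheads
at a node incident to an undirected edge; `ancestral_violations` reports —
but does not repair — departures from these constraints in a learned graph.

Assumptions: samples are independent draws from a fixed joint distribution
(or carry a known effective sample size, below); variables are categorical
with finitely many levels; missing entries are missing completely at random;
the distribution is faithful to the generating structure (conditional
independence ⇔ separation).  Orientation identifies the Markov equivalence
class only: chains and forks are observationally identical, which is why
unoriented ends remain circles rather than being guessed.

## Information estimators

All information quantities are plug-in estimates on contingency tables, in
nats.  Conditional mutual information is assembled from joint entropies,
I(X;Y|{A}) = −H(A) + H(X,A) + H(Y,A) − H(X,Y,A), and the conditional
3-point information is the difference I(X;Y;Z|{A}) = I(X;Y|{A}) −
I(X;Y|{A},Z), computed on a single complete-case sample so that the
decomposition and telescoping identities hold to machine precision (the
test suite checks 1e−12 on random tables).  Multivariate (interaction)
information uses the inclusion–exclusion sum over subset entropies and is
capped at 12 variables (2^p subsets).

With missing data, every estimate uses the Nₐ rows complete on the exact
variable tuple involved; Nₐ is recomputed per tuple (MCAR assumption).
Single-level variables are informationless, never errors: they contribute
zero with a warning, so degenerate inputs cannot abort a pipeline run.

## Finite-size penalties

Decisions use the penalized information I′ = I − k/n.  Two penalties are
implemented:

* **BIC/MDL**: k = ½ (r_X−1)(r_Y−1) ∏ᵢ r_{Aᵢ} · ln n — the usual
  parameter-count penalty.
* **NML** (default): a decomposable normalized-maximum-likelihood regret
  built from the multinomial parametric complexity C(K, n):
  k = ½(k_X + k_Y) with k_X = Σ_{u∈strata({A}×Y)} ln C(r_X, n_u) −
  Σ_{v∈strata({A})} ln C(r_X, n_v), and symmetrically for Y.  This form is
  decomposable over conditioning strata, symmetric in X and Y, reduces to
  the factorized-NML regret on a single stratum, and converges to the BIC
  penalty as n → ∞ at fixed dimensions.  Empty strata contribute zero
  (ln C(K, 0) = 0) and the total is clipped at zero.

C(K, n) follows the linear recurrence C(K,n) = C(K−1,n) + n/(K−2)·C(K−2,n)
in log space with memoization; C(2, n) is computed by exact summation up to
n = 1000 and by the Szpankowski expansion
ln C(2,n) ≈ ½ ln(nπ/2) + √(8/(9nπ)) + (3π−16)/(36nπ) above (relative error
≲ 1e−7 at the crossover, checked in the tests).  NML is the default because
it penalizes sparse strata more honestly than a flat parameter count on
small samples; BIC remains available via `complexity="bic"`.

## Step 1 — skeleton

From the complete graph, a cheap pre-pass removes every pair with
unconditional I′(X;Y) ≤ 0 (their separating set is empty).  Each surviving
edge then collects contributors one at a time: the candidate Z maximizing
the penalized gain I′₃ = I(X;Y;Z|{Aᵢ}) − Δdf/(2n) among positive
candidates, where Δdf = (r_X−1)(r_Y−1)∏ᵢr_{Aᵢ}(r_Z−1).  The penalty here
is deliberately the χ² null-bias scale, not the full model-complexity
regret: the plug-in 3-point estimate is itself biased downward by about
Δdf/2n when Z is uninformative, so this gate is a one-sided significance
test at the natural fluctuation scale, while the full regret would
double-count finite size and stall weak but genuine contributors (the
model-complexity guard sits in the removal test, where it belongs).
Edges are
processed by descending rank R = n·I′(best candidate); after extending an
edge's contributor list, the edge is removed if I′(X;Y|{Aᵢ}) ≤ 0 (the list
becomes its separating-set certificate), otherwise its next candidate and
rank are refreshed.  Only the touched edge is re-ranked per iteration (lazy
refresh); ties break lexicographically on (x, y, candidate), making runs
deterministic.  The exact published form of the rank is not available to
this implementation; n·I′ of the best next contributor is a monotone
surrogate that preserves the ordering semantics.

With `latent=True` (default) candidates come from all observed variables
minus the pair; with `latent=False`, only from current neighbors of X or Y,
as in classical constraint-based methods.  The full search is what licenses
conditional-independence conclusions under latent confounding, where
separating sets may require variables non-adjacent to both endpoints.
The greedy one-at-a-time collection is a deliberate trade: it avoids the
combinatorial subset search, at the cost of occasionally stalling on pairs
whose separating set has no individually-positive first step.

## Step 2 — confidence and signs

P_XY = min(1, exp(−n·I′(X;Y|{Aᵢ}))) is the probability that the edge
should be removed; using the penalized I′ absorbs the unknown normalization
into the complexity term.  The confidence ratio C_XY = P_XY/⟨P_XY^rand⟩
averages the same probability over B column-permuted replicates (default
B = 100; all columns are permuted independently per replicate, missing
positions traveling with their values, and all edges share the same seeded
replicates).  A ratio needs far fewer permutations than a p-value for
strong edges, where essentially every permutation gives P_rand ≈ 1.  By
default each replicate re-runs the per-pair contributor search; `fast_mode`
uses the unconditional I′ instead (a documented approximation).  Ratios are
computed in log space, so values like e^(−700) survive.  Filtering drops
edges with C_XY ≥ threshold; Step 2 runs only when a `ConfidenceConfig` is
supplied (the probabilities and signs are always computed).

Edge signs are the sign of the partial correlation of the integer-coded
levels of X and Y given the edge's contributors, read off the inverse
correlation matrix (plain correlation when there are no usable
contributors); degenerate cases return 0.  Level coding is first-appearance
order, echoed in the run report.

## Step 3 — orientation

For each unshielded triple ⟨X, Z, Y⟩ the conditioning set is the stored
separating set of (X, Y) minus Z — the certificate of their non-adjacency —
falling back to the collected contributors if the pair was filtered rather
than removed.  The raw 3-point value is shrunk toward zero by its
complexity increment (I′₃ = I₃ ∓ k₃/n, clipped at 0), so weak triples land
at probability ½ and are never oriented; the v-structure probability is the
logistic p = 1/(1 + exp(n·I′₃)).  The published probability expression is
not available to this implementation; the logistic is the simplest
calibrated map consistent with the sign semantics and the "probability >
½" stopping rule.

Triples are applied greedily by descending probability: negative triples
set arrowheads into Z (v-structure) where the marks are still circles;
positive triples propagate an existing arrowhead X*→Z into Z→Y.  Earlier
(higher-probability) assignments are never overwritten — conflicts are
logged — and the loop re-scans until no applicable triple with p > ½
remains, so propagation opportunities created by earlier orientations are
picked up regardless of initial order.  Orientation never changes the
skeleton.  No further completion rules (discriminating paths, etc.) are
applied; the output is a partially oriented pattern, not a maximally
informative PAG.

## Effective sample size

For autocorrelated rows the variance of empirical means is inflated by
Σₙ C(n); under an exponential decay C(n) = C(0)αⁿ the inflation sums to
(1+α)/(1−α), giving N_eff = N(1−α)/(1+α).  The estimator computes the
variance-weighted average autocorrelation of the centered integer-coded
series, fits a least-squares line to ln c(n) over the lags with c(n) above
a 0.05 floor (at most 50 lags; both config-exposed), and exponentiates the
slope, clipping α to [0, 1−1e−6).  All-negative autocorrelations give
α = 0.  N_eff then replaces N in every penalty and probability
(`DataTable.with_n_eff` / `PipelineConfig.n_eff`).  When the decay is a
mixture of time scales the single-exponential fit is conservative (it
under-estimates N_eff), which errs on the side of fewer claimed edges.

## Benchmark machinery

* **Random DAGs**: fixed topological order, each forward pair an edge with
  probability avg_degree/(P−1); level counts uniform on [2, 4]; CPT rows
  symmetric Dirichlet(1).  These are generic ("faithful almost surely")
  parameters.
* **Latent hiding**: uniformly among nodes with a significant topological
  effect — at least one child, and not parentless with a single child.
* **Oracle reference graphs**: the skeleton+orientation pipeline with
  conditional-independence decisions answered exactly by d-separation on
  the full DAG (hidden nodes included), restricted to observed variables.
  This is the method's own oracle fixpoint, not a certified complete PAG —
  a documented limitation.  Exhaustive subset search makes it exact but
  exponential; it is intended for small benchmark graphs.
* **Ising systems**: a reference network's DAG edges become symmetric
  couplings k_ij; each magnitude is found by bisecting the exact
  isolated-pair Boltzmann mutual information against the target MI
  estimated from binarized forward samples of the reference net (median
  split with a fallback when the integer median lands on the mode).  The
  pairwise inversion is deterministic and reproducible; it ignores
  collective effects, so whole-system MI can deviate from the target —
  acceptable for benchmarks whose point is symmetric (non-causal)
  dependence.  Unattainable targets clamp at the coupling bound with a
  warning.
* **Metropolis sampling**: proposals flip each spin independently with
  probability f (initial 0.10), accepted with min(1, exp(−ΔE)); f adapts
  multiplicatively toward 50% acceptance during burn-in (default 5000
  proposals, clipped to [0.01, 0.5]) and is then frozen; the chain state is
  recorded every post-burn-in iteration.  Recording every iteration (not
  only acceptances) is what makes the sample marginals converge to the
  Boltzmann distribution; the records are autocorrelated by construction,
  which is precisely what the effective-sample module corrects.  Strongly
  coupled systems can have a single-flip acceptance ceiling below 50%; the
  controller then sits at the ceiling.

## Evaluation

Skeleton metrics compare unordered adjacencies.  Endpoint metrics mark a
true-positive adjacency as misoriented when either end differs in arrowhead
status (arrow vs tail-or-circle; tail vs circle is not penalized) and score
TP′ = TP − TP_mis, FP′ = FP + TP_mis, with the recall denominator staying
at the reference edge count.  Conventions: precision 0 when nothing is
predicted but edges exist; all metrics 1 when both graphs are empty.

## What the synthetic benchmarks do and do not show

The generators emulate the structural features that matter to the method —
faithful multinomial dependencies, hidden confounders with topological
effect, symmetric non-causal couplings, Markovian autocorrelation.  They do
not emulate selection bias, measurement error, deterministic relations,
non-stationarity, or missingness that is informative rather than MCAR.
Passing the suite therefore demonstrates correctness of the estimators and
algorithms under the model's assumptions, not performance on data that
violate them.

## Problem sizes and reproducibility

The shipped study conditions: information identities on 1,000 random
tables; oracle exactness over every labeled DAG on ≤ 5 nodes (29,852
graphs); latent-signature recovery at N = 50,000; skeleton recovery on 20
random networks with P = 20, average degree 2, N = 10,000; a 15-spin
calibrated Ising chain with 30,000 consecutive Metropolis records analyzed
at N_eff; a two-state Markov chain of length 100,000 with α = 0.8; runtime
scaling over N ∈ {1,000; 5,000; 25,000} at P = 20.  All randomness flows
from explicit seeds; identical data, configuration and seed give
byte-identical edge summaries.
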