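# causalmi

Learning causal and non-causal graphical models — with latent variables —
from purely observational categorical data.

## The problem

Given N samples of P categorical variables (gene expression states, mutation
calls, genomic annotations, survey answers …), which dependencies are direct,
which are mediated, and which are causal?  Without time series or
interventions, the only usable signature of causality is the *unshielded
collider* (v-structure): two variables X and Y that are independent, yet
both associated with a third variable Z, force the orientations
X → Z ← Y.  Unobserved common causes complicate everything: they induce
associations between their observed children and leave their mark as
*bidirected* edges (Z ↔ Y) in the class of ancestral graphs.

`causalmi` implements a constraint-based reconstruction built entirely on
multivariate information:

1. **Skeleton** — starting from the complete graph, each pair (X, Y)
   iteratively collects the conditioning variables ("contributors") that
   best explain its mutual information, using the decomposition
   I(X;Y) = I(X;Y;{Aᵢ}) + I(X;Y|{Aᵢ}) and the iterative update
   I(X;Y;{Aᵢ}ₙ) = I(X;Y;{Aᵢ}ₙ₋₁) + I(X;Y;Aₙ|{Aᵢ}ₙ₋₁).  The next
   contributor maximizes the penalized gain I′(X;Y;Aₙ|{Aᵢ}) > 0; the edge
   is removed once I′(X;Y|{Aᵢ}) ≤ 0, where I′ = I − k/n subtracts a
   finite-size complexity k (BIC/MDL or a decomposable NML regret).
   Searching contributors among **all** observed variables (not just
   neighbors) keeps the procedure sound under latent confounding.
2. **Confidence** — each retained edge gets a removal probability
   P_XY = min(1, exp(−n·I′(X;Y|{Aᵢ}))) and a permutation ratio
   C_XY = P_XY / ⟨P_XY^rand⟩; filtering at C_XY < 10⁻³ keeps only strongly
   supported edges.  Signs come from partial correlations of the
   integer-coded levels.
3. **Orientation** — the sign of the conditional 3-point information
   I(X;Y;Z|{Aᵢ}) = I(X;Y|{Aᵢ}) − I(X;Y|{Aᵢ},Z) scores every unshielded
   triple: significantly negative ⇒ collider X → Z ← Y, significantly
   positive ⇒ propagate an existing arrowhead to Z → Y.  Triples are
   processed by decreasing probability p = 1/(1 + exp(n·I′₃)); edges with
   arrowheads at both ends become bidirected — the latent-cause signature.

For autocorrelated inputs (consecutive Monte Carlo records, repeated
measurements) the effective sample size N_eff = N(1−α)/(1+α), with α the
fitted per-step autocorrelation decay, replaces N in every finite-size term.

The package also ships the benchmark machinery: random DAGs with Dirichlet
CPTs and forward sampling, latent-variable hiding with a topological
eligibility rule, a d-separation oracle and oracle reference graphs, Ising
models calibrated to a reference network's pairwise mutual information with
Metropolis sampling, and skeleton/endpoint-aware precision–recall–F scoring.

## A worked example

```python
import numpy as np
from causalmi import DataTable, PipelineConfig, run_pipeline

rng = np.random.default_rng(0)
n = 10000
a = rng.integers(0, 2, n)                       # two independent causes
b = rng.integers(0, 2, n)
c = (rng.random(n) < 0.15 + 0.35 * (a + b)).astype(int)   # common effect

data = DataTable(np.column_stack([a, b, c]), ["A", "B", "C"], [["0", "1"]] * 3)
graph, states, report = run_pipeline(data, PipelineConfig(seed=0))
for (u, v) in graph.edges():
    print(u, graph.get_mark(u, v, u), graph.get_mark(u, v, v), v,
          graph.category(u, v))
```

prints

```
A circle arrow C partially-oriented
B circle arrow C partially-oriented
```

Both edges carry an arrowhead at C and none elsewhere: the data alone
identify C as the common effect of A and B (the circle ends stay
undetermined, as they should — a cause or a latent confounder of A would be
indistinguishable).  The removed pair is recorded with its separating set
(`states[("A","B")].sep_set == []`: A and B are marginally independent).
The `examples/` directory has one short script per capability: collider
orientation, latent-confounder detection (bidirected edges), effective
sample size, non-causal Ising benchmarks, and benchmark scoring.

A thin CLI mirrors the library:

```bash
causalmi simulate-bn -p 20 -n 10000 --seed 1 --net-out net.json -o data.tsv
causalmi reconstruct data.tsv -o edges.tsv --report report.json
causalmi neff correlated.tsv
causalmi evaluate --pred edges.tsv --ref reference.tsv --mode endpoint
```

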