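"""Benchmark ground-truth generation.

Two families of benchmarks:

* Causal: random DAGs with multinomial conditional probability tables,
  forward (ancestral) sampling, hiding of latent variables with a
  topological-effect eligibility rule, a d-separation oracle, and the oracle
  reference graph (the fixpoint the data-driven pipeline should converge to,
  with conditional-independence decisions answered exactly on the full DAG
  including hidden nodes).

* Non-causal: Ising-like spin systems whose symmetric couplings are
  calibrated to reproduce the pairwise mutual information of a reference
  Bayesian network, sampled by Metropolis Monte Carlo.  The accepted
  configurations are recorded consecutively and are therefore autocorrelated
  by design — the effective-sample-size module exists for exactly this.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx
import numpy as np

from .datatable import DataTable
from .graph import MixedGraph
from .orientation import TripleScore, orient

__all__ = [
    "BayesNet", "IsingModel", "random_dag", "forward_sample", "hide_latents",
    "d_separated", "oracle_reference_graph", "pair_mutual_information",
    "ising_calibrate", "metropolis_sample",
]


# ---------------------------------------------------------------------------
# Bayesian networks


@dataclass
class BayesNet:
    """DAG + per-node conditional probability tables.

    ``cpts[v]`` has shape (levels of parents..., levels of v) with parent
    axes in ``parents[v]`` order; every row sums to 1.
    """

    nodes: list[str]                      # topological order
    parents: dict[str, list[str]]
    levels: dict[str, int]
    cpts: dict[str, np.ndarray]
    _dag: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for v, ps in self.parents.items():
            for p in ps:
                g.add_edge(p, v)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent structure is cyclic")
        for v in self.nodes:
            shape = tuple(self.levels[p] for p in self.parents[v]) + (self.levels[v],)
            cpt = np.asarray(self.cpts[v], dtype=float)
            if cpt.shape != shape:
                raise ValueError(f"CPT shape mismatch for {v}")
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows of {v} do not sum to 1")
        self._dag = g

    @property
    def dag(self) -> nx.DiGraph:
        return self._dag

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._dag.edges())

    def to_json(self, path) -> None:
        obj = {"nodes": self.nodes,
               "parents": self.parents,
               "levels": self.levels,
               "cpts": {v: self.cpts[v].tolist() for v in self.nodes}}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "BayesNet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["nodes"], obj["parents"],
                   {k: int(v) for k, v in obj["levels"].items()},
                   {k: np.array(v) for k, v in obj["cpts"].items()})


def random_dag(p: int, avg_degree: float, level_range: tuple[int, int] = (2, 4),
               seed: int = 0) -> BayesNet:
    """Random DAG with symmetric-Dirichlet(1) CPTs.

    Nodes take a fixed topological order; each forward pair is an edge with
    probability avg_degree / (p - 1), giving the requested expected degree.
    Level counts are uniform over ``level_range`` (inclusive).
    """
    if p < 2 or not (0 < avg_degree < p - 1):
        raise ValueError("need p >= 2 and 0 < avg_degree < p-1")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(p - 1)))
    nodes = [f"V{i:0{width}d}" for i in range(p)]
    q = avg_degree / (p - 1)
    parents = {v: [] for v in nodes}
    for i, j in combinations(range(p), 2):
        if rng.random() < q:
            parents[nodes[j]].append(nodes[i])
    levels = {v: int(rng.integers(level_range[0], level_range[1] + 1))
              for v in nodes}
    cpts = {}
    for v in nodes:
        shape = tuple(levels[u] for u in parents[v]) + (levels[v],)
        n_rows = int(np.prod(shape[:-1])) if len(shape) > 1 else 1
        rows = rng.dirichlet(np.ones(levels[v]), size=n_rows)
        cpts[v] = rows.reshape(shape)
    return BayesNet(nodes, parents, levels, cpts)


def forward_sample(bn: BayesNet, n: int, seed: int = 0) -> DataTable:
    """Ancestral sampling: n complete rows in topological order."""
    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(bn.dag))
    cols = {v: np.zeros(n, dtype=np.int64) for v in bn.nodes}
    for v in order:
        ps = bn.parents[v]
        cpt = bn.cpts[v]
        r = bn.levels[v]
        if not ps:
            cols[v] = rng.choice(r, size=n, p=cpt)
            continue
        # stratify rows by parent configuration
        pconf = np.zeros(n, dtype=np.int64)
        for u in ps:
            pconf = pconf * bn.levels[u] + cols[u]
        flat = cpt.reshape(-1, r)
        out = np.zeros(n, dtype=np.int64)
        for conf in np.unique(pconf):
            sel = pconf == conf
            out[sel] = rng.choice(r, size=int(sel.sum()), p=flat[conf])
        cols[v] = out
    values = np.column_stack([cols[v] for v in bn.nodes])
    levels = [[str(k) for k in range(bn.levels[v])] for v in bn.nodes]
    return DataTable(values, list(bn.nodes), levels)


def hide_latents(bn: BayesNet, fraction_or_count: float, seed: int = 0
                 ) -> tuple[list[str], list[str]]:
    """Pick latent variables with a significant topological effect.

    Eligible nodes must have at least one child and must not be parentless
    with a single child (hiding those would not change the observable
    structure).  A value < 1 is a fraction of all nodes (rounded), otherwise
    a count.
    """
    eligible = []
    for v in bn.nodes:
        n_children = bn.dag.out_degree(v)
        if n_children == 0:
            continue
        if not bn.parents[v] and n_children == 1:
            continue
        eligible.append(v)
    if fraction_or_count < 1:
        count = int(round(fraction_or_count * len(bn.nodes)))
    else:
        count = int(fraction_or_count)
    if count > len(eligible):
        raise ValueError(f"requested {count} latents but only "
                         f"{len(eligible)} eligible nodes")
    rng = np.random.default_rng(seed)
    hidden = sorted(rng.choice(eligible, size=count, replace=False).tolist())
    observed = [v for v in bn.nodes if v not in set(hidden)]
    return observed, hidden


def d_separated(dag: nx.DiGraph | BayesNet, x: str, y: str, s=()) -> bool:
    """Standard d-separation (reachability) answer on a DAG."""
    g = dag.dag if isinstance(dag, BayesNet) else dag
    for node in (x, y, *s):
        if node not in g:
            raise KeyError(f"unknown node {node!r}")
    if x == y or x in s or y in s:
        raise ValueError("x, y must be distinct and not in the conditioning set")
    return nx.is_d_separator(g, {x}, {y}, set(s))


def oracle_reference_graph(bn: BayesNet, hidden=()) -> MixedGraph:
    """Reference mixed graph from a d-separation oracle on the full DAG.

    Runs the skeleton + orientation pipeline with conditional-independence
    decisions answered exactly by d-separation on the complete DAG (hidden
    nodes included), restricted to observed variables.  This is the fixpoint
    of the data-driven method, not a certified complete PAG.
    """
    hidden = set(hidden)
    observed = [v for v in bn.nodes if v not in hidden]
    dag = bn.dag
    # skeleton: remove any pair separable by a subset of observed variables
    sep: dict[tuple[str, str], list[str] | None] = {}
    graph = MixedGraph(observed)
    memo: dict[tuple[str, str, frozenset], bool] = {}

    def dsep(x, y, s):
        key = (x, y, frozenset(s))
        if key not in memo:
            memo[key] = nx.is_d_separator(dag, {x}, {y}, set(s))
        return memo[key]

    for x, y in combinations(observed, 2):
        rest = [v for v in observed if v not in (x, y)]
        found = None
        for size in range(len(rest) + 1):
            for s in combinations(rest, size):
                if dsep(x, y, s):
                    found = list(s)
                    break
            if found is not None:
                break
        sep[(x, y)] = found
        if found is None:
            graph.add_edge(x, y)

    # orientation from oracle triple verdicts: z outside the separating set
    # of (x, y) is a collider, inside is a chain/fork
    triples: list[TripleScore] = []
    for z in observed:
        nbrs = sorted(graph.neighbors(z))
        for x, y in combinations(nbrs, 2):
            if graph.has_edge(x, y):
                continue
            s = sep[(x, y) if (x, y) in sep else (y, x)]
            if s is None:     # pragma: no cover - non-adjacent implies separable
                continue
            if z in s:
                triples.append(TripleScore(x, z, y, 1.0, 1000, 0.999, "non-v"))
            else:
                triples.append(TripleScore(x, z, y, -1.0, 1000, 1.0, "v"))
    return orient(graph, triples)


# ---------------------------------------------------------------------------
# Ising-like systems


@dataclass
class IsingModel:
    """Binary spins x_i = +-1 with symmetric pair couplings.

    Energy of a configuration: E = -sum_edges k_ij x_i x_j.
    """

    nodes: list[str]
    couplings: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        fixed = {}
        for (u, v), k in self.couplings.items():
            fixed[(u, v) if u <= v else (v, u)] = float(k)
        self.couplings = fixed
        nodeset = set(self.nodes)
        for (u, v) in self.couplings:
            if u not in nodeset or v not in nodeset:
                raise KeyError(f"coupling on unknown nodes ({u}, {v})")

    def energy(self, config: dict[str, int] | np.ndarray) -> float:
        if isinstance(config, np.ndarray):
            config = dict(zip(self.nodes, config))
        return -sum(k * config[u] * config[v]
                    for (u, v), k in self.couplings.items())


def pair_mutual_information(k: float) -> float:
    """Exact MI of an isolated two-spin system with coupling k (nats).

    From the 4-state Boltzmann distribution: uniform marginals and
    P(x1 = x2) = e^k / (e^k + e^-k).
    """
    w = np.array([math.exp(k), math.exp(-k), math.exp(-k), math.exp(k)])
    p = w / w.sum()
    # marginals are uniform (1/2, 1/2) by symmetry
    return float((p * np.log(4 * p)).sum())


def _binarize(data: DataTable) -> np.ndarray:
    """Median split of each column's codes into +-1 spins."""
    out = np.empty(data.values.shape, dtype=np.int8)
    for j in range(data.n_vars):
        col = data.values[:, j]
        med = np.median(col)
        hi = col > med
        if hi.all() or not hi.any():   # integer median landed on the mode
            hi = col >= med
        out[:, j] = np.where(hi, 1, -1)
    return out


def ising_calibrate(reference_bn: BayesNet,
                    coupling_bounds: tuple[float, float] = (0.0, 5.0),
                    mc_budget: int = 20000, seed: int = 0,
                    tol: float = 1e-6) -> IsingModel:
    """Couplings matching the reference network's pairwise mutual information.

    The reference Bayes net is forward-sampled (``mc_budget`` rows) and
    binarized by median split; for every edge of its DAG the empirical
    pairwise MI becomes the target, and the coupling magnitude is found by
    bisecting the exact isolated-pair Boltzmann MI.  The coupling sign
    follows the sign of the binarized pair correlation.  Targets above the
    upper bound's MI are clamped with a warning.
    """
    lo, hi = coupling_bounds
    if not (0 <= lo < hi):
        raise ValueError("need 0 <= lower bound < upper bound")
    sample = forward_sample(reference_bn, mc_budget, seed=seed)
    spins = _binarize(sample)
    col = {v: j for j, v in enumerate(sample.columns)}
    couplings: dict[tuple[str, str], float] = {}
    for (u, v) in reference_bn.edges():
        a, b = spins[:, col[u]].astype(float), spins[:, col[v]].astype(float)
        target = _empirical_pair_mi(a, b)
        corr = float(np.mean(a * b) - a.mean() * b.mean())
        if target <= tol:
            couplings[(u, v)] = 0.0
            continue
        if pair_mutual_information(hi) < target:
            warnings.warn(f"target MI {target:.4f} for edge ({u},{v}) "
                          f"unattainable at bound {hi}; clamped")
            k = hi
        else:
            a_, b_ = lo, hi
            while b_ - a_ > tol:
                m = 0.5 * (a_ + b_)
                if pair_mutual_information(m) < target:
                    a_ = m
                else:
                    b_ = m
            k = 0.5 * (a_ + b_)
        couplings[(u, v)] = k if corr >= 0 else -k
    return IsingModel(list(reference_bn.nodes), couplings)


def _empirical_pair_mi(a: np.ndarray, b: np.ndarray) -> float:
    n = a.size
    mi = 0.0
    for va, vb in product((-1, 1), repeat=2):
        pab = np.mean((a == va) & (b == vb))
        pa, pb = np.mean(a == va), np.mean(b == vb)
        if pab > 0:
            mi += pab * math.log(pab / (pa * pb))
    return mi


def metropolis_sample(model: IsingModel, n: int, seed: int = 0,
                      flip_fraction: float = 0.10, burn_in: int = 5000,
                      adapt_every: int = 500,
                      return_acceptance: bool = False):
    """Metropolis Monte Carlo sampling of an Ising-like model.

    Each proposal flips a random ~``flip_fraction`` of the spins and is
    accepted with probability min(1, exp(-dE)).  During burn-in the flip
    fraction is adapted multiplicatively every ``adapt_every`` proposals
    toward a 50% acceptance rate (clipped to [0.01, 0.5]) and then frozen.
    The chain state is recorded at every post-burn-in iteration, so
    successive samples are correlated by design — analyze them at the
    effective sample size, not at face value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = model.nodes
    p = len(nodes)
    idx = {v: j for j, v in enumerate(nodes)}
    # adjacency as index triples for fast local energy differences
    pairs = [(idx[u], idx[v], k) for (u, v), k in model.couplings.items()]
    state = rng.choice([-1, 1], size=p).astype(np.int8)

    def delta_e(flip: np.ndarray) -> float:
        d = 0.0
        for i, j, k in pairs:
            if flip[i] ^ flip[j]:          # exactly one endpoint flips
                d += 2.0 * k * state[i] * state[j]
        return d

    f = flip_fraction
    accepted_window = 0
    for step in range(1, burn_in + 1):
        flip = rng.random(p) < f
        if not flip.any():
            flip[rng.integers(p)] = True
        de = delta_e(flip)
        if de <= 0 or rng.random() < math.exp(-de):
            state[flip] *= -1
            accepted_window += 1
        if step % adapt_every == 0:
            rate = accepted_window / adapt_every
            f = min(0.5, max(0.01, f * max(rate, 0.02) / 0.5))
            accepted_window = 0

    records = np.empty((n, p), dtype=np.int8)
    accepted = 0
    for step in range(n):
        flip = rng.random(p) < f
        if not flip.any():
            flip[rng.integers(p)] = True
        de = delta_e(flip)
        if de <= 0 or rng.random() < math.exp(-de):
            state[flip] *= -1
            accepted += 1
        records[step] = state
    values = ((records + 1) // 2).astype(np.int64)   # -1 -> 0, +1 -> 1
    table = DataTable(values, list(nodes), [["-1", "1"] for _ in nodes])
    if return_acceptance:
        return table, accepted / n
    return table
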