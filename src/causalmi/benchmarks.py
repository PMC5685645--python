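"""Reusable benchmark routines: study-condition runs with scalar summaries.

Each function generates its own inputs from a seed, runs the method under
the stated conditions, and returns plain numbers, so the same code backs the
test suite and the reproduction script.
"""

from __future__ import annotations

import time
from itertools import combinations

import networkx as nx
import numpy as np

from .datatable import DataTable
from .effective_sample import effective_n, estimate_n_eff
from .evaluation import skeleton_metrics
from .graph import ARROW, MixedGraph
from .information import cond_mutual_info, multivariate_information, \
    three_point_info
from .pipeline import PipelineConfig, run_pipeline
from .simulation import BayesNet, forward_sample, ising_calibrate, \
    metropolis_sample, oracle_reference_graph, random_dag
from .skeleton import learn_skeleton

__all__ = [
    "random_table", "identity_residuals", "all_dags", "true_v_structures",
    "oracle_exactness", "fig_latent_collider_bn", "latent_recovery",
    "skeleton_recovery", "chain_bn", "noncausal_orientation",
    "markov_chain_table", "markov_neff_recovery", "skeleton_scaling",
    "printed_alpha_neff_ratio",
]


# ---------------------------------------------------------------------------
# information identities


def random_table(rng: np.random.Generator, n: int = 60,
                 max_levels: int = 3) -> DataTable:
    """Random categorical table of 3 variables for identity checks."""
    levels = [int(rng.integers(2, max_levels + 1)) for _ in range(3)]
    vals = np.column_stack([rng.integers(0, r, size=n) for r in levels])
    return DataTable(vals, ["X", "Y", "A"],
                     [[str(i) for i in range(r)] for r in levels])


def identity_residuals(n_tables: int = 1000, seed: int = 0) -> float:
    """Max |residual| of the information decomposition and telescoping sums.

    Checks, on random tables: I(X;Y) = I(X;Y|A) + I(X;Y;A), and the two-step
    telescoping I(X;Y) = I(X;Y;A) + I(X;Y;B|A) + I(X;Y|A,B) with B a fresh
    variable.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        t3 = random_table(rng)
        i_xy = cond_mutual_info(t3, "X", "Y", ()).info
        i_xy_a = cond_mutual_info(t3, "X", "Y", ("A",)).info
        i3 = multivariate_information(t3, ("X", "Y", "A"))
        worst = max(worst, abs(i_xy - i_xy_a - i3))
        # 4-variable telescoping
        n = t3.n_samples
        b = rng.integers(0, 2, size=n)
        t4 = DataTable(np.column_stack([t3.values, b]),
                       ["X", "Y", "A", "B"],
                       [list(l) for l in t3.levels] + [["0", "1"]])
        i_a = three_point_info(t4, "X", "Y", "A", ()).info
        i_b_a = three_point_info(t4, "X", "Y", "B", ("A",)).info
        i_rest = cond_mutual_info(t4, "X", "Y", ("A", "B")).info
        i_xy4 = cond_mutual_info(t4, "X", "Y", ()).info
        worst = max(worst, abs(i_xy4 - i_a - i_b_a - i_rest))
    return worst


# ---------------------------------------------------------------------------
# oracle exactness on small DAGs


def all_dags(p: int):
    """All labeled DAGs on p nodes (pair-state enumeration + acyclicity)."""
    nodes = [f"N{i}" for i in range(p)]
    pairs = list(combinations(range(p), 2))
    for state in np.ndindex(*([3] * len(pairs))):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (i, j), s in zip(pairs, state):
            if s == 1:
                g.add_edge(nodes[i], nodes[j])
            elif s == 2:
                g.add_edge(nodes[j], nodes[i])
        if nx.is_directed_acyclic_graph(g):
            yield g


def true_v_structures(dag: nx.DiGraph) -> set[tuple]:
    out = set()
    und = {frozenset(e) for e in dag.edges()}
    for z in dag.nodes:
        for x, y in combinations(sorted(dag.predecessors(z)), 2):
            if frozenset((x, y)) not in und:
                out.add((x, z, y))
    return out


def _dag_as_bn(dag: nx.DiGraph) -> BayesNet:
    """Wrap a DAG with placeholder uniform CPTs (oracle runs never sample)."""
    nodes = sorted(dag.nodes)
    parents = {v: sorted(dag.predecessors(v)) for v in nodes}
    cpts = {}
    for v in nodes:
        shape = tuple([2] * len(parents[v])) + (2,)
        cpts[v] = np.full(shape, 0.5)
    return BayesNet(nodes, parents, {v: 2 for v in nodes}, cpts)


def oracle_exactness(max_nodes: int = 5) -> dict:
    """Run the d-separation-oracle pipeline on every DAG of 2..max_nodes nodes.

    Returns DAG counts and the number of skeleton or v-structure mismatches
    against the generating DAG (both are zero when the pipeline is exact).
    """
    n_dags = 0
    skeleton_errors = 0
    v_errors = 0
    for p in range(2, max_nodes + 1):
        for dag in all_dags(p):
            n_dags += 1
            bn = _dag_as_bn(dag)
            og = oracle_reference_graph(bn)
            true_skel = {tuple(sorted(e)) for e in dag.edges()}
            if og.skeleton_edges() != true_skel:
                skeleton_errors += 1
                continue
            truth = true_v_structures(dag)
            found = set()
            for z in og.nodes:
                for x, y in combinations(sorted(og.neighbors(z)), 2):
                    if og.has_edge(x, y):
                        continue
                    if og.get_mark(x, z, z) == ARROW and \
                            og.get_mark(y, z, z) == ARROW:
                        found.add((x, z, y))
            if found != truth:
                v_errors += 1
    return {"n_dags": n_dags, "skeleton_errors": skeleton_errors,
            "v_structure_errors": v_errors}


# ---------------------------------------------------------------------------
# latent-confounder recovery


def _monotone_cpt(n_parents: int, strength: float = 1.6) -> np.ndarray:
    """Binary CPT, logistic in the sum of parent spins; root -> uniform."""
    if n_parents == 0:
        return np.array([0.5, 0.5])
    shape = tuple([2] * n_parents) + (2,)
    out = np.zeros(shape)
    for conf in np.ndindex(*shape[:-1]):
        s = sum(2 * c - 1 for c in conf)
        p1 = 1.0 / (1.0 + np.exp(-strength * s))
        out[conf] = [1 - p1, p1]
    return out


def fig_latent_collider_bn() -> BayesNet:
    """Collider path X -> Z <- L -> Y <- W with L unobservable.

    Hiding L leaves Z and Y dependent through their latent common cause, so
    the two v-structures X -> Z <- L(Y) and Z(L) -> Y <- W meet on the ZY
    edge, which must come out bidirected.
    """
    nodes = ["X", "W", "L", "Z", "Y"]
    parents = {"X": [], "W": [], "L": [], "Z": ["X", "L"], "Y": ["L", "W"]}
    cpts = {v: _monotone_cpt(len(parents[v])) for v in nodes}
    return BayesNet(nodes, parents, {v: 2 for v in nodes}, cpts)


def latent_recovery(n_samples: int = 50000, seed: int = 0) -> dict:
    """Oracle and data-driven recovery of the bidirected latent signature."""
    bn = fig_latent_collider_bn()
    og = oracle_reference_graph(bn, hidden=["L"])
    oracle_bi = int(og.has_edge("Y", "Z") and og.category("Y", "Z") == "bidirected")
    data = forward_sample(bn, n_samples, seed=seed)
    keep = [i for i, c in enumerate(data.columns) if c != "L"]
    sub = DataTable(data.values[:, keep], [data.columns[i] for i in keep],
                    [data.levels[i] for i in keep])
    graph, _, _ = run_pipeline(sub, PipelineConfig(seed=seed))
    data_bi = int(graph.has_edge("Y", "Z") and
                  graph.category("Y", "Z") == "bidirected")
    return {"oracle_bidirected": oracle_bi, "data_bidirected": data_bi}


# ---------------------------------------------------------------------------
# skeleton recovery on random networks


def skeleton_recovery(n_runs: int = 20, p: int = 20, avg_degree: float = 2.0,
                      n_samples: int = 10000, seed: int = 0) -> dict:
    """Mean skeleton F-score over random DAG benchmarks, no latents."""
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_runs):
        s = int(rng.integers(0, 2**31 - 1))
        bn = random_dag(p, avg_degree, seed=s)
        data = forward_sample(bn, n_samples, seed=s + 1)
        graph, _ = learn_skeleton(data)
        ref = MixedGraph(list(bn.nodes))
        for u, v in bn.edges():
            ref.add_edge(u, v)
        scores.append(skeleton_metrics(graph, ref).fscore)
    return {"mean_f": float(np.mean(scores)), "min_f": float(np.min(scores)),
            "n_runs": n_runs}


# ---------------------------------------------------------------------------
# non-causal (Ising) benchmark


def chain_bn(p: int = 15, strength: float = 1.6) -> BayesNet:
    """Binary Markov chain V0 -> V1 -> ... with monotone CPTs."""
    nodes = [f"V{i:02d}" for i in range(p)]
    parents = {nodes[0]: []}
    for i in range(1, p):
        parents[nodes[i]] = [nodes[i - 1]]
    cpts = {v: _monotone_cpt(len(parents[v]), strength) for v in nodes}
    return BayesNet(nodes, parents, {v: 2 for v in nodes}, cpts)


def noncausal_orientation(p: int = 15, n_samples: int = 30000,
                          seed: int = 0) -> dict:
    """Arrowhead fraction on Metropolis samples of a calibrated Ising chain.

    The couplings are symmetric by construction, so no causality exists;
    reconstruction at the effective sample size should orient (essentially)
    nothing.
    """
    bn = chain_bn(p)
    model = ising_calibrate(bn, seed=seed)
    data = metropolis_sample(model, n_samples, seed=seed + 1)
    fit = estimate_n_eff(data, max_lag=60)
    data = data.with_n_eff(fit.n_eff)
    graph, _, _ = run_pipeline(data, PipelineConfig(seed=seed))
    n_edges = graph.n_edges
    arrowed = sum(1 for (u, v) in graph.edges()
                  if ARROW in (graph.get_mark(u, v, u), graph.get_mark(u, v, v)))
    frac = arrowed / n_edges if n_edges else 0.0
    return {"arrowhead_fraction": frac, "n_edges": n_edges,
            "alpha": fit.alpha, "n_eff": fit.n_eff}


# ---------------------------------------------------------------------------
# effective-sample recovery and scaling


def markov_chain_table(n: int, alpha: float, seed: int = 0) -> DataTable:
    """Symmetric two-state Markov chain with autocorrelation alpha per step."""
    stay = (1.0 + alpha) / 2.0
    rng = np.random.default_rng(seed)
    x = np.zeros(n, dtype=np.int64)
    x[0] = rng.integers(0, 2)
    flips = rng.random(n - 1) > stay
    for i in range(1, n):
        x[i] = x[i - 1] ^ flips[i - 1]
    return DataTable(x[:, None], ["S"], [["0", "1"]])


def markov_neff_recovery(n_samples: int = 100000, alpha: float = 0.8,
                         seed: int = 0) -> dict:
    """Recover alpha and N_eff/N from a simulated two-state Markov chain."""
    data = markov_chain_table(n_samples, alpha, seed)
    fit = estimate_n_eff(data, max_lag=60)
    return {"alpha_hat": fit.alpha, "neff_ratio": fit.n_eff / n_samples,
            "neff_ratio_true": (1 - alpha) / (1 + alpha)}


def skeleton_scaling(p: int = 20, sizes=(1000, 5000, 25000),
                     seed: int = 0) -> dict:
    """log-log slope of Step-1 runtime versus sample size."""
    bn = random_dag(p, 2.0, seed=seed)
    data_full = forward_sample(bn, max(sizes), seed=seed + 1)
    times = []
    for n in sizes:
        sub = DataTable(data_full.values[:n], list(data_full.columns),
                        [list(l) for l in data_full.levels])
        t0 = time.time()
        learn_skeleton(sub)
        times.append(time.time() - t0)
    slope = float(np.polyfit(np.log(sizes), np.log(times), 1)[0])
    return {"slope": slope, "times_s": times, "sizes": list(sizes)}


def printed_alpha_neff_ratio(alpha: float, n: int = 1_000_000) -> float:
    """N_eff/N implied by a fitted per-step autocorrelation decay."""
    return effective_n(n, alpha) / n
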