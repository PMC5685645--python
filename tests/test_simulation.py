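"""Benchmark generators: Bayes nets, latent hiding, d-separation oracle,
Ising calibration and Metropolis sampling."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from causalmi import (cond_mutual_info, d_separated, forward_sample,
                      hide_latents, ising_calibrate, metropolis_sample,
                      oracle_reference_graph, pair_mutual_information,
                      random_dag)
from causalmi.simulation import BayesNet, IsingModel
from conftest import binary_bn


# ---------------------------------------------------------------------------
# random DAGs and forward sampling


def test_random_dag_reproducible_and_acyclic():
    a = random_dag(10, 3.0, seed=5)
    b = random_dag(10, 3.0, seed=5)
    assert a.edges() == b.edges()
    assert nx.is_directed_acyclic_graph(a.dag)
    for v in a.nodes:
        assert np.allclose(a.cpts[v].sum(axis=-1), 1.0)


def test_random_dag_average_degree():
    degs = []
    for s in range(60):
        bn = random_dag(12, 3.0, seed=s)
        degs.append(2 * len(bn.edges()) / 12)
    assert np.mean(degs) == pytest.approx(3.0, rel=0.10)


def test_random_dag_validation():
    with pytest.raises(ValueError):
        random_dag(1, 0.5)
    with pytest.raises(ValueError):
        random_dag(5, 4.5)


def test_forward_sample_deterministic_cpts():
    cpts = {"A": np.array([1.0, 0.0]),
            "B": np.array([[0.0, 1.0], [1.0, 0.0]])}
    bn = BayesNet(["A", "B"], {"A": [], "B": ["A"]}, {"A": 2, "B": 2}, cpts)
    t = forward_sample(bn, 50, seed=0)
    assert (t.values == [0, 1]).all()


def test_forward_sample_root_marginals(rng):
    p1 = 0.3
    bn = BayesNet(["A"], {"A": []}, {"A": 2}, {"A": np.array([1 - p1, p1])})
    t = forward_sample(bn, 10000, seed=4)
    freq = t.values.mean()
    sigma = math.sqrt(p1 * (1 - p1) / 10000)
    assert abs(freq - p1) <= 3 * sigma


def test_forward_sample_mi_matches_cpt_exact():
    """Empirical MI of a strong 2-node link vs the CPT-exact value."""
    bn = binary_bn({"A": [], "B": ["A"]}, strength=1.6)
    joint = bn.cpts["B"] * 0.5          # p(a) p(b|a), shape (2, 2)
    exact = sum(joint[a, b] * math.log(joint[a, b] /
                                       (joint[a].sum() * joint[:, b].sum()))
                for a in range(2) for b in range(2))
    t = forward_sample(bn, 50000, seed=8)
    est = cond_mutual_info(t, "A", "B", ()).info
    assert est == pytest.approx(exact, abs=0.01)


# ---------------------------------------------------------------------------
# latent hiding


def test_hide_latents_eligibility():
    # A -> B -> C; D -> C; E isolated-ish: E -> F (parentless single child)
    bn = binary_bn({"A": [], "B": ["A"], "C": ["B", "D"], "D": [],
                    "E": [], "F": ["E"]})
    for s in range(40):
        _, hidden = hide_latents(bn, 1, seed=s)
        # C, F childless; A, D, E parentless single-child: only B eligible
        assert hidden == ["B"]
    with pytest.raises(ValueError):
        hide_latents(bn, 2)


def test_hide_latents_fraction_rounding():
    bn = random_dag(37, 2.5, seed=1)
    eligible = [v for v in bn.nodes
                if bn.dag.out_degree(v) > 0
                and not (not bn.parents[v] and bn.dag.out_degree(v) == 1)]
    if len(eligible) >= 7:
        _, hidden = hide_latents(bn, 0.2, seed=2)
        assert len(hidden) == 7      # round(0.2 * 37)
        assert set(hidden) <= set(eligible)


# ---------------------------------------------------------------------------
# d-separation


def test_d_separation_chain_and_collider():
    g = nx.DiGraph([("A", "B"), ("B", "C")])
    assert d_separated(g, "A", "C", {"B"})
    assert not d_separated(g, "A", "C", set())
    g2 = nx.DiGraph([("A", "B"), ("C", "B")])
    assert d_separated(g2, "A", "C", set())
    assert not d_separated(g2, "A", "C", {"B"})
    with pytest.raises(KeyError):
        d_separated(g, "A", "Z", set())


def test_d_separation_matches_exact_ci():
    """d-separation verdicts equal exact CI checks on the enumerated joint.

    Generic (Dirichlet) parameters make the distribution faithful almost
    surely; symmetric hand-built CPTs can cancel and would not do here.
    """
    rng = np.random.default_rng(99)
    parents = {"A": [], "B": ["A"], "C": ["A"], "D": ["B", "C"]}
    cpts = {}
    for v, ps in parents.items():
        shape = tuple([2] * len(ps)) + (2,)
        n_rows = int(np.prod(shape[:-1])) if ps else 1
        cpts[v] = rng.dirichlet(np.ones(2), size=n_rows).reshape(shape)
    bn = BayesNet(list(parents), parents, {v: 2 for v in parents}, cpts)
    # enumerate the exact joint distribution
    names = bn.nodes
    joint = {}
    for assign in itertools.product((0, 1), repeat=4):
        a = dict(zip(names, assign))
        p = 1.0
        for v in names:
            idx = tuple(a[u] for u in bn.parents[v]) + (a[v],)
            p *= float(bn.cpts[v][idx])
        joint[assign] = p

    def exact_cmi(x, y, s):
        # I(X;Y|S) from the exact joint, zero iff conditional independence
        acc = 0.0
        ix, iy = names.index(x), names.index(y)
        is_ = [names.index(v) for v in s]
        for assign, p in joint.items():
            if p == 0:
                continue
            key_s = tuple(assign[i] for i in is_)
            p_xys = sum(q for a2, q in joint.items()
                        if tuple(a2[i] for i in is_) == key_s
                        and a2[ix] == assign[ix] and a2[iy] == assign[iy])
            p_xs = sum(q for a2, q in joint.items()
                       if tuple(a2[i] for i in is_) == key_s
                       and a2[ix] == assign[ix])
            p_ys = sum(q for a2, q in joint.items()
                       if tuple(a2[i] for i in is_) == key_s
                       and a2[iy] == assign[iy])
            p_s = sum(q for a2, q in joint.items()
                      if tuple(a2[i] for i in is_) == key_s)
            acc += p * math.log(p_xys * p_s / (p_xs * p_ys))
        return acc

    for x, y in itertools.combinations(names, 2):
        rest = [v for v in names if v not in (x, y)]
        for k in range(len(rest) + 1):
            for s in itertools.combinations(rest, k):
                dsep = d_separated(bn, x, y, set(s))
                ci = abs(exact_cmi(x, y, s)) < 1e-12
                assert dsep == ci, (x, y, s)


def test_latent_sepsets_require_nonadjacent_variable():
    """Synthetic two-latent topology: every observed separating set of (Z,T)
    contains W, which is itself non-adjacent to Z."""
    E = [("L", "Z"), ("L", "X"), ("L2", "T"), ("L2", "Y"),
         ("W", "X"), ("W", "Y"), ("X", "Y"), ("Y", "T")]
    g = nx.DiGraph(E)
    rest = ["X", "Y", "W"]
    seps = [set(s) for k in range(4) for s in itertools.combinations(rest, k)
            if d_separated(g, "Z", "T", set(s))]
    assert seps and all("W" in s for s in seps)
    assert d_separated(g, "Z", "T", {"X", "Y", "W"})
    # conditioning through the latents also works, but they are unobservable
    assert d_separated(g, "Z", "T", {"X", "L"})
    assert d_separated(g, "Z", "T", {"Y", "L2"})
    # W is separable from Z (non-adjacent in the oracle graph)
    assert d_separated(g, "W", "Z", set())


# ---------------------------------------------------------------------------
# oracle reference graphs


def test_oracle_no_hidden_matches_dag(collider_data):
    _, bn = collider_data
    og = oracle_reference_graph(bn)
    assert og.skeleton_edges() == {("A", "C"), ("B", "C")}
    assert og.get_mark("A", "C", "C") == "arrow"
    assert og.get_mark("B", "C", "C") == "arrow"


def test_oracle_latent_bidirected():
    from causalmi.benchmarks import fig_latent_collider_bn
    og = oracle_reference_graph(fig_latent_collider_bn(), hidden=["L"])
    assert og.category("Y", "Z") == "bidirected"


def test_oracle_matches_data_driven_at_large_n():
    from causalmi import learn_skeleton
    bn = binary_bn({"A": [], "B": ["A"], "C": ["B"], "D": ["B"], "E": ["D"]})
    data = forward_sample(bn, 50000, seed=13)
    graph, _ = learn_skeleton(data)
    og = oracle_reference_graph(bn)
    assert graph.skeleton_edges() == og.skeleton_edges()


def test_oracle_bidirected_implies_hidden_common_cause():
    """On 5-node nets, a bidirected edge appears only between nodes sharing a
    hidden ancestor-cause."""
    for s in range(20):
        bn = random_dag(5, 2.0, seed=s)
        eligible = [v for v in bn.nodes
                    if bn.dag.out_degree(v) > 0
                    and not (not bn.parents[v] and bn.dag.out_degree(v) == 1)]
        if not eligible:
            continue
        _, hidden = hide_latents(bn, 1, seed=s)
        og = oracle_reference_graph(bn, hidden=hidden)
        anc = {v: nx.ancestors(bn.dag, v) | {v} for v in bn.nodes}
        for (u, v) in og.edges():
            if og.category(u, v) == "bidirected":
                shared_hidden = [h for h in hidden
                                 if u in nx.descendants(bn.dag, h)
                                 and v in nx.descendants(bn.dag, h)]
                assert shared_hidden, (s, u, v)


# ---------------------------------------------------------------------------
# Ising systems


def test_pair_mi_closed_form():
    assert pair_mutual_information(0.0) == 0.0
    # monotone and symmetric in |k|
    ks = [0.1, 0.5, 1.0, 2.0]
    mis = [pair_mutual_information(k) for k in ks]
    assert mis == sorted(mis)
    assert pair_mutual_information(-0.7) == pytest.approx(
        pair_mutual_information(0.7), abs=1e-12)


def test_ising_calibration_recovers_coupling():
    """Bisection inverts the exact two-spin MI to high precision."""
    k_true = 0.8
    target = pair_mutual_information(k_true)
    lo, hi = 0.0, 5.0
    while hi - lo > 1e-9:
        m = 0.5 * (lo + hi)
        if pair_mutual_information(m) < target:
            lo = m
        else:
            hi = m
    assert 0.5 * (lo + hi) == pytest.approx(k_true, abs=1e-3)


def test_ising_calibrate_zero_target():
    bn = binary_bn({"A": [], "B": ["A"]}, strength=0.0)   # independent link
    model = ising_calibrate(bn, seed=1)
    assert model.couplings[("A", "B")] == pytest.approx(0.0, abs=0.02)


def test_ising_calibrate_symmetric_keys():
    from causalmi.benchmarks import chain_bn
    model = ising_calibrate(chain_bn(6), seed=2)
    for (u, v) in model.couplings:
        assert u <= v


def test_metropolis_zero_couplings_uniform():
    model = IsingModel(["a", "b", "c"], {})
    t, acc = metropolis_sample(model, 4000, seed=3, return_acceptance=True)
    assert acc == 1.0           # dE = 0 always
    freq = t.values.mean(axis=0)
    assert np.all(np.abs(freq - 0.5) < 3 * math.sqrt(0.25 / 4000))


def test_metropolis_two_spin_boltzmann():
    model = IsingModel(["a", "b"], {("a", "b"): 0.5})
    t = metropolis_sample(model, 100000, seed=4)
    p_same = np.mean(t.values[:, 0] == t.values[:, 1])
    expected = math.exp(0.5) / (math.exp(0.5) + math.exp(-0.5))
    assert p_same == pytest.approx(expected, abs=0.02)


def test_metropolis_acceptance_adapts():
    """Burn-in adaptation lands the acceptance rate near the 50% target
    (on a moderately coupled system where that target is attainable)."""
    nodes = [f"s{i}" for i in range(8)]
    model = IsingModel(nodes, {(nodes[i], nodes[i + 1]): 0.35
                               for i in range(7)})
    _, acc = metropolis_sample(model, 20000, seed=6, return_acceptance=True)
    assert 0.4 <= acc <= 0.6


def test_metropolis_autocorrelation_vs_blocked_variance():
    """Fitted decay agrees with a blocked-variance effective-size estimate."""
    from causalmi import estimate_n_eff
    from causalmi.benchmarks import chain_bn
    model = ising_calibrate(chain_bn(8), seed=7)
    t = metropolis_sample(model, 40000, seed=8)
    fit = estimate_n_eff(t, max_lag=60)
    # blocked-variance estimate averaged over spins: n_eff = var(x) / Var(mean),
    # converted to the implied per-step decay via r = (1-a)/(1+a)
    n = t.n_samples
    block = 1000
    n_blocks = n // block
    ratios = []
    for j in range(t.n_vars):
        x = 2.0 * t.values[:n_blocks * block, j] - 1
        means = x.reshape(n_blocks, block).mean(axis=1)
        var_mean = means.var(ddof=1) / n_blocks
        if var_mean > 0:
            ratios.append(x.var(ddof=1) / var_mean / n)
    r_blocked = float(np.mean(ratios))
    alpha_blocked = (1 - r_blocked) / (1 + r_blocked)
    assert fit.alpha == pytest.approx(alpha_blocked, rel=0.2)


def test_bayesnet_json_roundtrip(tmp_path):
    bn = random_dag(6, 2.0, seed=9)
    path = tmp_path / "net.json"
    bn.to_json(path)
    back = BayesNet.from_json(path)
    assert back.edges() == bn.edges()
    for v in bn.nodes:
        assert np.allclose(back.cpts[v], bn.cpts[v])
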