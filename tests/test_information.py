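"""Information estimators: entropies, (conditional) mutual information,
multinomial complexity, and their exact identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import entropy as scipy_entropy

from causalmi import (DataTable, complexity_term, cond_mutual_info,
                      contingency, entropy, log_multinomial_complexity,
                      multivariate_information, three_point_info)
from conftest import make_table


# ---------------------------------------------------------------------------
# contingency tables and complete-case handling


def test_contingency_counts_and_complete_cases():
    t = make_table([[0, 0], [0, 1], [1, 0], [1, 1]])
    ct = contingency(t, ("X0", "X1"))
    assert ct.counts.sum() == 4 and ct.n_available == 4
    assert ct.counts.tolist() == [[1, 1], [1, 1]]


def test_contingency_missing_row_rule():
    t = make_table([[0, 0], [0, 1], [1, 0], [1, 1]])
    t.missing_mask[0, 0] = True
    assert contingency(t, ("X0", "X1")).n_available == 3
    assert contingency(t, ("X1",)).n_available == 4


def test_contingency_disjoint_missingness_matches_row_scan(rng):
    vals = rng.integers(0, 3, size=(50, 3))
    mask = rng.random((50, 3)) < 0.2
    t = DataTable(vals, ["X", "Y", "Z"], [["0", "1", "2"]] * 3, mask)
    ct = contingency(t, ("X", "Y", "Z"))
    expected = sum(1 for i in range(50) if not mask[i].any())
    assert ct.n_available == expected == ct.counts.sum()


def test_contingency_errors():
    t = make_table([[0, 0], [1, 1]])
    with pytest.raises(KeyError):
        contingency(t, ("nope",))
    t.missing_mask[:, 0] = True
    with pytest.raises(ValueError):
        contingency(t, ("X0",))


# ---------------------------------------------------------------------------
# entropy


@pytest.mark.parametrize("counts, expected", [
    ((2, 2), math.log(2)),
    ((4, 0), 0.0),
    ((3, 1), 0.5623351446188083),   # -(3/4 ln 3/4 + 1/4 ln 1/4)
])
def test_entropy_values(counts, expected):
    assert entropy(np.array(counts)) == pytest.approx(expected, abs=1e-12)


def test_entropy_agrees_with_scipy(rng):
    for _ in range(50):
        counts = rng.integers(0, 20, size=rng.integers(2, 10))
        if counts.sum() == 0:
            continue
        assert entropy(counts) == pytest.approx(
            scipy_entropy(counts / counts.sum()), abs=1e-12)


# ---------------------------------------------------------------------------
# mutual information


def test_mi_small_table_value():
    # joint counts [[2,1],[1,2]] over N=6, plug-in formula by hand
    t = make_table([[0, 0], [0, 0], [0, 1], [1, 0], [1, 1], [1, 1]])
    r = cond_mutual_info(t, "X0", "X1", ())
    p = np.array([[2, 1], [1, 2]]) / 6
    expected = sum(p[i, j] * math.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
                   for i in range(2) for j in range(2))
    assert r.info == pytest.approx(expected, abs=1e-12)
    assert r.info == pytest.approx(0.0566, abs=1e-4)


def test_mi_identical_uniform_binary(rng):
    x = rng.integers(0, 2, 1000)
    t = make_table(np.column_stack([x, x]))
    assert cond_mutual_info(t, "X0", "X1", ()).info == pytest.approx(
        math.log(2), abs=0.01)


def test_decomposition_identity(rng):
    """I(X;Y) = I(X;Y|A) + I(X;Y;A) to machine precision on random tables."""
    for _ in range(100):
        t = make_table(rng.integers(0, 3, size=(40, 3)), ["X", "Y", "A"])
        i_xy = cond_mutual_info(t, "X", "Y", ()).info
        i_xy_a = cond_mutual_info(t, "X", "Y", ("A",)).info
        i3 = multivariate_information(t, ("X", "Y", "A"))
        assert abs(i_xy - i_xy_a - i3) < 1e-12


def test_telescoping_identity(rng):
    """I(X;Y) = I(X;Y;A1) + I(X;Y;A2|A1) + I(X;Y|A1,A2), any ordering."""
    for _ in range(50):
        t = make_table(rng.integers(0, 2, size=(60, 4)), ["X", "Y", "A", "B"])
        i_xy = cond_mutual_info(t, "X", "Y", ()).info
        for order in (("A", "B"), ("B", "A")):
            s = (three_point_info(t, "X", "Y", order[0], ()).info
                 + three_point_info(t, "X", "Y", order[1], (order[0],)).info
                 + cond_mutual_info(t, "X", "Y", order).info)
            assert abs(i_xy - s) < 1e-12


@given(st.lists(st.integers(0, 2), min_size=12, max_size=60),
       st.lists(st.integers(0, 2), min_size=12, max_size=60),
       st.lists(st.integers(0, 1), min_size=12, max_size=60))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_decomposition_identity_hypothesis(xs, ys, zs):
    """The decomposition I(X;Y) = I(X;Y|A) + I(X;Y;A) is an algebraic
    identity of the plug-in estimators, whatever the data."""
    n = min(len(xs), len(ys), len(zs))
    vals = np.column_stack([xs[:n], ys[:n], zs[:n]])
    t = make_table(vals, ["X", "Y", "A"])
    i_xy = cond_mutual_info(t, "X", "Y", ()).info
    i_xy_a = cond_mutual_info(t, "X", "Y", ("A",)).info
    i3 = multivariate_information(t, ("X", "Y", "A"))
    assert abs(i_xy - i_xy_a - i3) < 1e-12


def test_degenerate_single_level_warns():
    t = DataTable(np.zeros((10, 2), dtype=int), ["X", "Y"],
                  [["only"], ["0"]])
    with pytest.warns(UserWarning, match="single level"):
        r = cond_mutual_info(t, "X", "Y", ())
    assert r.info == 0.0


# ---------------------------------------------------------------------------
# multivariate (interaction) information


def test_multivariate_two_point_equals_mi(rng):
    t = make_table(rng.integers(0, 3, size=(80, 2)), ["X", "Y"])
    assert multivariate_information(t, ("X", "Y")) == pytest.approx(
        cond_mutual_info(t, "X", "Y", ()).info, abs=1e-12)


def test_xor_triple_interaction_is_minus_ln2():
    # Z = X xor Y on the full uniform support: H pairs = 2 ln 2, H triple = 2 ln 2
    rows = [[x, y, x ^ y] for x in (0, 1) for y in (0, 1)]
    t = make_table(np.array(rows * 5), ["X", "Y", "Z"])
    assert multivariate_information(t, ("X", "Y", "Z")) == pytest.approx(
        -math.log(2), abs=1e-12)


def test_independent_product_table_zero():
    rows = [[x, y] for x in (0, 1) for y in (0, 1, 2)]
    t = make_table(np.array(rows * 4), ["X", "Y"])
    assert multivariate_information(t, ("X", "Y")) == pytest.approx(0, abs=1e-12)


def test_three_point_collider_sign(collider_data):
    data, _ = collider_data
    r = three_point_info(data, "A", "B", "C", ())
    # conditioning on the collider creates dependence: negative 3-point info
    assert r.info < -0.01


def test_three_point_chain_sign(chain_data):
    data, _ = chain_data
    assert three_point_info(data, "A", "C", "B", ()).info > 0.01


def test_too_many_variables_rejected():
    t = make_table(np.zeros((4, 2), dtype=int))
    with pytest.raises(ValueError):
        multivariate_information(t, tuple("abcdefghijklm"))


# ---------------------------------------------------------------------------
# multinomial complexity


def _log_c_bruteforce(k: int, n: int) -> float:
    """Direct summation over compositions h1+...+hk = n."""
    from itertools import product
    total = 0.0
    for h in product(range(n + 1), repeat=k):
        if sum(h) != n:
            continue
        logmult = gammaln(n + 1) - sum(gammaln(hi + 1) for hi in h)
        loglik = sum(hi * math.log(hi / n) for hi in h if hi > 0)
        total += math.exp(logmult + loglik)
    return math.log(total)


@pytest.mark.parametrize("k,n,expected", [
    (1, 0, 0.0), (1, 7, 0.0), (1, 1000, 0.0),
    (2, 1, math.log(2)),
    (2, 2, math.log(2.5)),
])
def test_log_complexity_known_values(k, n, expected):
    assert log_multinomial_complexity(k, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("k", [2, 3, 4, 5])
@pytest.mark.parametrize("n", [1, 3, 8, 15])
def test_log_complexity_matches_bruteforce(k, n):
    assert log_multinomial_complexity(k, n) == pytest.approx(
        _log_c_bruteforce(k, n), rel=1e-10)


def test_log_complexity_asymptotic_continuity():
    from causalmi.information import _log_c2_exact
    # expansion used above the exact-summation cutoff agrees to ~1e-6
    for n in (900, 1000):
        exact = _log_c2_exact(n)
        approx = (0.5 * math.log(n * math.pi / 2)
                  + math.sqrt(8 / (9 * n * math.pi))
                  + (3 * math.pi - 16) / (36 * n * math.pi))
        assert approx == pytest.approx(exact, rel=1e-6)


def test_complexity_bic_formula(rng):
    t = make_table(rng.integers(0, 2, size=(100, 2)), ["X", "Y"])
    assert complexity_term(t, "X", "Y", (), "bic") == pytest.approx(
        0.5 * math.log(100), abs=1e-12)


def test_complexity_nml_single_level_contributes_zero():
    t = DataTable(np.column_stack([np.zeros(20, int),
                                   np.arange(20) % 2]),
                  ["X", "Y"], [["a"], ["0", "1"]])
    # the single-level side contributes nothing; Y side strata are equal
    assert complexity_term(t, "X", "Y", (), "nml") == pytest.approx(0.0, abs=1e-12)


def test_nml_to_bic_ratio_approaches_one():
    ratios = []
    for n in (100, 10000, 1000000):
        vals = np.column_stack([np.arange(n) % 2, (np.arange(n) // 2) % 2])
        t = make_table(vals, ["X", "Y"])
        ratios.append(complexity_term(t, "X", "Y", (), "nml")
                      / complexity_term(t, "X", "Y", (), "bic"))
    assert abs(ratios[-1] - 1) < abs(ratios[0] - 1)
    assert ratios[-1] == pytest.approx(1.0, abs=0.15)


def test_complexity_nonnegative(rng):
    for _ in range(20):
        t = make_table(rng.integers(0, 3, size=(50, 3)), ["X", "Y", "A"])
        for mode in ("bic", "nml"):
            assert complexity_term(t, "X", "Y", ("A",), mode) >= 0


# ---------------------------------------------------------------------------
# n_eff override


def test_n_eff_override_monotone(rng):
    vals = rng.integers(0, 2, size=(1000, 2))
    vals[:, 1] = vals[:, 0] ^ (rng.random(1000) < 0.3)
    t = make_table(vals, ["X", "Y"])
    shifted = []
    for n_eff in (50, 200, 1000):
        r = cond_mutual_info(t.with_n_eff(n_eff), "X", "Y", ())
        assert r.n_used == n_eff
        shifted.append(r.shifted)
    assert shifted == sorted(shifted)


def test_shifted_definition_exact(rng):
    t = make_table(rng.integers(0, 3, size=(200, 3)), ["X", "Y", "A"])
    r = cond_mutual_info(t, "X", "Y", ("A",))
    assert r.shifted == r.info - r.complexity / r.n_used
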