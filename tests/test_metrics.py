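"""Correlation, ranking and docking metrics against independent oracles.

Kendall tau-b and the Predictive Index are checked against exhaustive pair
enumeration; the worked closed-form values were computed by hand from the
definitions before being frozen here.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akscore.metrics import (DockingCase, RankingGroup, UndefinedMetricError,
                             bootstrap_compare, docking_power, kendall_tau,
                             mae, pearson_r, predictive_index, ranking_power,
                             rmse, spearman_rho)


# ---------------------------------------------------------------------------
# brute-force oracles

def tau_b_by_enumeration(x, y):
    nc = nd = t = u = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[j] - x[i], y[j] - y[i]
        if dx == 0 and dy == 0:
            continue
        elif dx == 0:
            t += 1
        elif dy == 0:
            u += 1
        elif dx * dy > 0:
            nc += 1
        else:
            nd += 1
    denom = np.sqrt((nc + nd + t) * (nc + nd + u))
    return (nc - nd) / denom if denom else np.nan


def pi_by_enumeration(pred, y, pearlman=False):
    num = den = 0.0
    for i, j in itertools.combinations(range(len(y)), 2):
        w = abs(y[j] - y[i])
        prod = np.sign(pred[j] - pred[i]) * np.sign(y[j] - y[i])
        s = np.sign(prod) if pearlman else float(prod > 0)
        num += w * s
        den += w
    return num / den


# ---------------------------------------------------------------------------
# worked examples

def test_pearson_affine_and_reversal():
    x = np.array([1.0, 2.0, 5.0, 7.0])
    assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)


def test_pearson_closed_form_example():
    assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / np.sqrt(84))


def test_pearson_undefined_for_constant_input():
    with pytest.raises(UndefinedMetricError):
        pearson_r([1.0, 1.0, 1.0], [1, 2, 3])


def test_spearman_monotone_and_reversed():
    x = np.array([0.3, 1.1, 4.0, 9.2, 11.0])
    assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman_rho(x, x[::-1].copy() * 0 - x) == pytest.approx(-1.0)


def test_spearman_tie_case_matches_rank_pearson():
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    # average ranks computed by hand: x -> 1, 2.5, 2.5, 4, 5
    rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
    ry = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    expected = pearson_r(rx, ry)
    assert spearman_rho(x, y) == pytest.approx(expected)


def test_kendall_tie_example():
    # pairs: (1,2) concordant, (1,3) concordant, (2,3) tied in x only
    assert kendall_tau([1, 2, 2], [1, 2, 3]) == pytest.approx(2 / np.sqrt(6))


def test_kendall_perfect_and_reversed():
    x = [3.0, 1.0, 4.0, 1.5, 5.0]
    assert kendall_tau(x, x) == pytest.approx(1.0)
    assert kendall_tau(x, [-v for v in x]) == pytest.approx(-1.0)


def test_predictive_index_worked_example():
    y = np.array([1.0, 3.0, 6.0])
    pred = np.array([1.0, 6.0, 3.0])
    assert predictive_index(pred, y) == pytest.approx(0.7)
    assert predictive_index(pred, y, mode="pearlman") == pytest.approx(0.4)


def test_predictive_index_extremes():
    y = np.array([1.0, 2.0, 4.0, 9.0])
    assert predictive_index(y, y) == pytest.approx(1.0)
    assert predictive_index(-y, y) == pytest.approx(0.0)          # binary mode
    assert predictive_index(-y, y, mode="pearlman") == pytest.approx(-1.0)


def test_mae_rmse_examples():
    y = np.zeros(2)
    assert mae([1.0, -1.0], y) == pytest.approx(1.0)
    assert rmse([1.0, -1.0], y) == pytest.approx(1.0)
    assert mae([0.0, 3.0], y) == pytest.approx(1.5)
    assert rmse([0.0, 3.0], y) == pytest.approx(np.sqrt(4.5))
    assert mae(y, y) == 0.0 and rmse(y, y) == 0.0


# ---------------------------------------------------------------------------
# exhaustive oracle equivalence

@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_tau_and_pi_match_enumeration_on_all_permutations(n):
    y = np.arange(1.0, n + 1)
    for perm in itertools.permutations(range(n)):
        pred = np.array(perm, dtype=float) + 1
        assert kendall_tau(pred, y) == pytest.approx(tau_b_by_enumeration(pred, y))
        assert predictive_index(pred, y) == pytest.approx(pi_by_enumeration(pred, y))
        assert predictive_index(pred, y, mode="pearlman") == pytest.approx(
            pi_by_enumeration(pred, y, pearlman=True))


def test_tau_and_pi_match_enumeration_with_ties(rng):
    for _ in range(50):
        n = int(rng.integers(3, 7))
        pred = rng.integers(0, 3, n).astype(float)   # many ties
        y = rng.integers(0, 4, n).astype(float)
        if np.ptp(pred) == 0 or np.ptp(y) == 0:
            continue
        assert kendall_tau(pred, y) == pytest.approx(tau_b_by_enumeration(pred, y))
        assert predictive_index(pred, y) == pytest.approx(pi_by_enumeration(pred, y))


# ---------------------------------------------------------------------------
# properties

@settings(deadline=None, max_examples=60)
@given(st.lists(st.integers(-50, 50), min_size=3, max_size=12, unique=True),
       st.integers(0, 10 ** 6))
def test_rank_metrics_invariant_under_monotone_transform(xs, seed):
    # integer inputs keep transformed values separated beyond the 1e-6
    # tie-rounding resolution
    y = np.random.default_rng(seed).normal(size=len(xs))
    if np.ptp(np.round(y, 6)) == 0:
        return
    x = np.array(xs, dtype=float)
    fx = np.exp(x / 50.0) + 3.0   # strictly increasing
    assert spearman_rho(fx, y) == pytest.approx(spearman_rho(x, y), abs=1e-9)
    assert kendall_tau(fx, y) == pytest.approx(kendall_tau(x, y), abs=1e-9)
    assert predictive_index(fx, y) == pytest.approx(predictive_index(x, y), abs=1e-9)


@settings(deadline=None, max_examples=60)
@given(st.integers(2, 40), st.integers(0, 10 ** 6))
def test_rmse_never_below_mae(n, seed):
    r = np.random.default_rng(seed)
    pred, y = r.normal(size=n), r.normal(size=n)
    assert rmse(pred, y) >= mae(pred, y) - 1e-12


def test_pi_ranges(rng):
    for _ in range(100):
        n = int(rng.integers(3, 8))
        pred, y = rng.normal(size=n), rng.normal(size=n)
        assert 0.0 <= predictive_index(pred, y) <= 1.0
        assert -1.0 <= predictive_index(pred, y, mode="pearlman") <= 1.0


# ---------------------------------------------------------------------------
# ranking power over clusters

def _group(gid, exp, pred):
    return RankingGroup(gid, [(f"{gid}m{i}", e, p)
                              for i, (e, p) in enumerate(zip(exp, pred))])


def test_ranking_power_perfect_and_mixed():
    exp = [1.0, 2.0, 3.0, 4.0, 5.0]
    perfect = [_group("a", exp, exp), _group("b", exp, [2 * e for e in exp])]
    assert ranking_power(perfect) == pytest.approx((1.0, 1.0, 1.0))
    mixed = [_group("a", exp, exp), _group("b", exp, exp[::-1])]
    sp, kt, pi = ranking_power(mixed)
    assert sp == pytest.approx(0.0)
    assert kt == pytest.approx(0.0)
    assert pi == pytest.approx(0.5)  # binary-mode PI: (1 + 0) / 2


def test_ranking_power_matches_per_group_oracle(rng):
    groups = []
    for g in range(10):
        exp = rng.normal(size=5)
        pred = rng.normal(size=5)
        groups.append(_group(f"g{g}", exp, pred))
    sp, kt, pi = ranking_power(groups)
    sp_ref = np.mean([spearman_rho(g.predicted, g.experimental) for g in groups])
    kt_ref = np.mean([tau_b_by_enumeration(np.round(g.predicted, 6),
                                           np.round(g.experimental, 6))
                      for g in groups])
    pi_ref = np.mean([pi_by_enumeration(np.round(g.predicted, 6),
                                        np.round(g.experimental, 6))
                      for g in groups])
    assert sp == pytest.approx(sp_ref)
    assert kt == pytest.approx(kt_ref)
    assert pi == pytest.approx(pi_ref)


def test_ranking_power_enforces_cluster_size():
    bad = [_group("a", [1, 2, 3], [1, 2, 3])]
    with pytest.raises(ValueError):
        ranking_power(bad)
    ranking_power(bad, group_size=None)  # relaxed


# ---------------------------------------------------------------------------
# docking power

def test_docking_power_native_always_best():
    cases = [DockingCase(f"c{i}", -10.0, [-5.0, -4.0, -3.0]) for i in range(4)]
    assert docking_power(cases) == pytest.approx((1.0, 1.0, 1.0))


def test_docking_power_native_third():
    cases = [DockingCase(f"c{i}", -8.0, [-10.0, -9.0, -3.0]) for i in range(4)]
    assert docking_power(cases) == pytest.approx((0.0, 0.0, 1.0))


def test_docking_power_counts_planted_ranks(rng):
    cases, expected = [], np.zeros(3)
    for i in range(50):
        decoys = np.sort(rng.normal(-6, 2, size=20))
        rank = int(rng.integers(1, 6))
        # native placed strictly between decoys rank-1 and rank
        if rank == 1:
            native = decoys[0] - 1.0
        else:
            native = (decoys[rank - 2] + decoys[rank - 1]) / 2
        cases.append(DockingCase(f"c{i}", float(native), list(decoys)))
        for k in range(3):
            expected[k] += rank <= k + 1
    assert docking_power(cases) == pytest.approx(tuple(expected / 50))


def test_docking_power_larger_is_better_mode():
    cases = [DockingCase("c", 9.0, [5.0, 6.0])]
    assert docking_power(cases, larger_is_better=True) == (1.0, 1.0, 1.0)
    assert docking_power(cases) == (0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# bootstrap comparison

def test_bootstrap_self_comparison_t_near_zero(rng):
    y = rng.normal(size=120)
    pred = y + rng.normal(0, 0.3, 120)
    res = bootstrap_compare(pred, pred, y, n_boot=1000, seed=5)
    assert abs(res.t_pearson) < 0.1
    assert abs(res.t_rmse) < 0.1
    assert res.resample_size == int(np.ceil(2 / 3 * 120))


def test_bootstrap_separates_signal_from_shuffled(rng):
    # t_pearson is bounded by the shuffled predictor's resample spread
    # (~ sqrt(resample size)), so the set must be large enough for t > 20
    n = 800
    y = rng.normal(size=n)
    good = y + rng.normal(0, 0.1, n)
    bad = rng.permutation(y)
    res = bootstrap_compare(good, bad, y, n_boot=400, seed=7)
    assert res.t_pearson > 20
    assert res.t_rmse < -20  # the good predictor has much lower RMSE
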