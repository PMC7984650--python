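"""Splits, metrics, stacking bonus, bootstrap CIs, channel comparisons."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from transtack import (
    bootstrap_median_ci,
    compare_channels,
    mean_absolute_error,
    monte_carlo_splits,
    r_squared,
    stacking_bonus,
)


# ------------------------------------------------------------------- splits

def _twin_groups(n, n_pairs):
    groups = [f"fam{i}" for i in range(n_pairs) for _ in (0, 1)]
    groups += [f"solo{i}" for i in range(n - 2 * n_pairs)]
    return np.array(groups)


def test_families_never_straddle_and_sizes_bounded():
    n, n_pairs = 200, 50
    groups = _twin_groups(n, n_pairs)
    plan = monte_carlo_splits(n, groups, n_splits=100, test_fraction=0.3, seed=0)
    target = round(0.3 * n)
    for train, test in plan:
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == n
        test_set = set(test)
        for g in np.unique(groups):
            members = set(np.flatnonzero(groups == g))
            assert members <= test_set or members.isdisjoint(test_set)
        assert abs(len(test) - target) <= 2  # within one family of the target


def test_splits_deterministic_given_seed():
    groups = _twin_groups(60, 10)
    a = monte_carlo_splits(60, groups, n_splits=5, seed=3)
    b = monte_carlo_splits(60, groups, n_splits=5, seed=3)
    for (tr1, te1), (tr2, te2) in zip(a, b):
        np.testing.assert_array_equal(te1, te2)
        np.testing.assert_array_equal(tr1, tr2)


def test_five_twin_families_enumerated_allocation():
    # 10 subjects in 5 families of 2, test fraction 0.3 -> target 3 subjects,
    # reachable only with whole families: the test side holds 1 or 2 of them
    groups = np.repeat([f"f{i}" for i in range(5)], 2)
    plan = monte_carlo_splits(10, groups, n_splits=50, test_fraction=0.3, seed=1)
    for _, test in plan:
        fams = {groups[i] for i in test}
        assert len(fams) in (1, 2)
        assert len(test) == 2 * len(fams)


def test_oversized_family_rejected():
    groups = np.array(["big"] * 8 + ["a", "b"])
    with pytest.raises(ValueError):
        monte_carlo_splits(10, groups, n_splits=1, test_fraction=0.3, seed=0)


def test_stratified_splits_balance_response_bins(rng):
    n = 200
    groups = np.array([f"s{i}" for i in range(n)])
    y = np.sort(rng.standard_normal(n))
    plan = monte_carlo_splits(n, groups, strata=y, n_splits=20,
                              test_fraction=0.3, seed=2)
    for train, test in plan:
        assert abs(len(test) - 60) <= 2
        # each response quintile contributes ~30% of its members
        for q in range(5):
            members = np.arange(q * 40, (q + 1) * 40)
            frac = np.isin(members, test).mean()
            assert 0.1 <= frac <= 0.5


# ------------------------------------------------------------------ metrics

def test_r_squared_reference_points():
    y = np.array([0., 1., 2.])
    assert r_squared(y, y) == pytest.approx(1.0)
    assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
    assert r_squared(y, np.zeros(3)) == pytest.approx(1 - 5 / 2)  # hand arithmetic
    with pytest.raises(ValueError):
        r_squared(np.ones(4), np.ones(4))


def test_mean_absolute_error_cases(rng):
    assert mean_absolute_error([1., 3.], [2., 2.]) == pytest.approx(1.0)
    v = rng.standard_normal(10)
    assert mean_absolute_error(v, v) == 0.0
    w = rng.standard_normal(10)
    perm = rng.permutation(10)
    assert mean_absolute_error(v, w) == pytest.approx(
        mean_absolute_error(v[perm], w[perm]))


def test_stacking_bonus_hand_oracle():
    singles = [0.1, 0.2, 0.0, -0.1, 0.05]
    assert stacking_bonus(0.25, singles, "mean") == pytest.approx(0.20)
    assert stacking_bonus(0.25, singles, "best") == pytest.approx(0.05)
    assert stacking_bonus(0.2, [0.2, 0.1], "best") == pytest.approx(0.0)
    with pytest.raises(ValueError):
        stacking_bonus(0.1, [])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1, 1), min_size=1, max_size=8), st.floats(-1, 1))
def test_bonus_best_never_exceeds_bonus_mean(singles, r2_stack):
    assert (stacking_bonus(r2_stack, singles, "best")
            <= stacking_bonus(r2_stack, singles, "mean") + 1e-12)


# ---------------------------------------------------------------- bootstrap

def test_bootstrap_constant_vector_degenerates_to_point():
    assert bootstrap_median_ci(np.full(7, 3.5), seed=0) == (3.5, 3.5, 3.5)


def test_bootstrap_ci_within_attainable_medians():
    values = np.array([1.0, 5.0, 9.0])
    # full enumeration: median of any resample of 3 is one of the 3 values
    attainable = {np.median(r) for r in product(values, repeat=3)}
    med, lo, hi = bootstrap_median_ci(values, n_boot=4000, seed=1)
    assert med == 5.0 and lo in attainable and hi in attainable
    assert lo <= med <= hi


def test_bootstrap_deterministic_given_seed(rng):
    v = rng.standard_normal(20)
    assert bootstrap_median_ci(v, seed=9) == bootstrap_median_ci(v, seed=9)


# ----------------------------------------------------------------- wilcoxon

def test_compare_channels_exact_enumeration_oracle():
    # absolute differences are all distinct so ranks are unambiguous
    a = np.array([1.2, 0.8, 1.5, 0.35, 2.0, 1.1])
    b = np.array([1.0, 0.9, 1.1, 0.2, 1.5, 1.4])
    p, _ = compare_channels(a, b)
    # exhaustive null: all 2^6 sign assignments of the |difference| ranks
    d = a - b
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    null = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in product([0, 1], repeat=6)]
    p_exact = np.mean([w >= observed for w in null])
    assert p == pytest.approx(p_exact)


def test_compare_channels_effect_size_extremes(rng):
    base = rng.standard_normal(10)
    _, rb = compare_channels(base + 1.0, base)  # strictly greater everywhere
    assert rb == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        p, rb = compare_channels(base, base)
    assert p == 1.0 and rb == 0.0


def test_compare_channels_requires_pairs():
    with pytest.raises(ValueError):
        compare_channels([1, 2, 3], [1, 2])
    with pytest.raises(ValueError):
        compare_channels([1, 2, 3], [3, 2, 1])
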