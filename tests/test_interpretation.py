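"""Encoding patterns, max-abs rescaling, strength maps, grouped summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from transtack import (
    EncodingPattern,
    encoding_pattern,
    group_average_loadings,
    maxabs_rescale,
    refit_full,
    strength_map,
)
from transtack.simulate import SimulationConfig, generate_cohort


def _whitened(rng, n=50, p=6):
    """Data whose sample covariance is exactly the identity."""
    X = rng.standard_normal((n, p))
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    L = np.linalg.cholesky(cov)
    return Xc @ np.linalg.inv(L).T


def test_identity_covariance_returns_weights(rng):
    X = _whitened(rng)
    w = rng.standard_normal(6)
    np.testing.assert_allclose(encoding_pattern(w, X).loadings, w, atol=1e-10)


def test_two_feature_analytic_case(rng):
    cov = np.array([[1.0, 0.5], [0.5, 1.0]])
    X = _whitened(rng, n=40, p=2) @ np.linalg.cholesky(cov).T
    A = encoding_pattern(np.array([1.0, -1.0]), X).loadings
    np.testing.assert_allclose(A, [0.5, -0.5], atol=1e-10)


def test_zero_weights_and_linearity(rng):
    X = rng.standard_normal((30, 8))
    assert np.all(encoding_pattern(np.zeros(8), X).loadings == 0)
    w1, w2 = rng.standard_normal(8), rng.standard_normal(8)
    lhs = encoding_pattern(2.0 * w1 - 3.0 * w2, X).loadings
    rhs = (2.0 * encoding_pattern(w1, X).loadings
           - 3.0 * encoding_pattern(w2, X).loadings)
    assert np.abs(lhs - rhs).max() < 1e-8


def test_implicit_covariance_path_matches_explicit(rng):
    X = rng.standard_normal((60, 200))
    w = rng.standard_normal(200)
    Xc = X - X.mean(axis=0)
    explicit = (Xc.T @ Xc / 59) @ w
    assert np.abs(encoding_pattern(w, X).loadings - explicit).max() < 1e-8


def test_encoding_dimension_mismatch(rng):
    with pytest.raises(ValueError):
        encoding_pattern(np.zeros(5), rng.standard_normal((10, 4)))


# ----------------------------------------------------------------- rescaling

def test_maxabs_rescale_cases():
    np.testing.assert_allclose(maxabs_rescale(np.array([2., -4., 0.])),
                               [0.5, -1.0, 0.0])
    z = maxabs_rescale(np.zeros(4))
    assert np.all(z == 0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_maxabs_preserves_signs_and_zeros(seed):
    v = np.random.default_rng(seed).standard_normal(12)
    v[::4] = 0.0
    r = maxabs_rescale(v)
    np.testing.assert_array_equal(np.sign(r), np.sign(v))
    assert np.abs(r).max() <= 1.0


# -------------------------------------------------------------- strength map

def test_strength_map_hand_built_oracle():
    links = np.array([1.0, 0.0, 2.0])  # pairs (0,1), (0,2), (1,2)
    np.testing.assert_allclose(strength_map(links, 3, top_fraction=1.0),
                               [1.0, 3.0, 2.0])
    np.testing.assert_allclose(strength_map(links, 3, top_fraction=1 / 3),
                               [0.0, 2.0, 2.0])  # only the largest link kept
    assert np.all(strength_map(np.zeros(3), 3) == 0)


def test_strength_map_full_fraction_equals_absolute_row_sums(rng):
    p = 8
    links = rng.standard_normal(p * (p - 1) // 2)
    from transtack import devectorize_upper_triangle
    expected = np.abs(devectorize_upper_triangle(links, p)).sum(axis=1)
    np.testing.assert_allclose(strength_map(links, p, 1.0), expected)


def test_strength_map_length_check():
    with pytest.raises(ValueError):
        strength_map(np.zeros(4), 3)


# ---------------------------------------------------------- grouped loadings

def _pattern(loadings, labels):
    return EncodingPattern(channel="lc", loadings=np.asarray(loadings, float),
                           feature_labels=labels)


def test_group_average_loadings_by_sign():
    pattern = _pattern([0.2, 0.4, -0.1, 0.3, 0.0, 0.0],
                       ["a1", "a2", "b1", "b2", "c1", "c2"])
    grouping = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    pos = group_average_loadings(pattern, grouping, "positive")
    assert pos.set_index("group").loc["A", "mean_loading"] == pytest.approx(0.3)
    assert pos.set_index("group").loc["B", "mean_loading"] == pytest.approx(0.3)
    assert np.isnan(pos.set_index("group").loc["C", "mean_loading"])  # zeros count as neither
    neg = group_average_loadings(pattern, grouping, "negative")
    assert neg.set_index("group").loc["B", "mean_loading"] == pytest.approx(-0.1)
    assert np.isnan(neg.set_index("group").loc["A", "mean_loading"])
    with pytest.raises(ValueError):
        group_average_loadings(pattern, {}, "positive")


def test_group_average_counts_ungrouped():
    pattern = _pattern([0.5, -0.5, 0.1], ["x", "y", "stray"])
    out = group_average_loadings(pattern, {"x": "G", "y": "G"}, "positive")
    assert out.attrs["n_ungrouped"] == 1


# ----------------------------------------------------------------- refitting

def test_refit_full_screens_by_meta_coefficient_ci():
    cfg = SimulationConfig(n_subjects=120, channel_dims=(40, 40),
                           shared_loading_fraction=(0.0, 0.0),
                           unique_loading_fraction=(0.4, 0.0),
                           twin_fraction=0.0, seed=3)
    cohort = generate_cohort(cfg)
    coef_summary = pd.DataFrame({
        "channel": ["channel0", "channel1"],
        "median": [0.8, 0.01],
        "ci_low": [0.6, -0.01],  # channel1's CI contains zero
        "ci_high": [1.0, 0.05],
    })
    results, skipped = refit_full(cohort.channels, cohort.response.values,
                                  coef_summary, seed=0)
    assert skipped == ["channel1"]
    model, pattern = results["channel0"]
    assert pattern.rescaled and pattern.loadings.size == 40
    assert np.abs(pattern.loadings).max() <= 1.0


def test_refit_full_no_survivors_is_empty():
    cfg = SimulationConfig(n_subjects=60, channel_dims=(10,),
                           shared_loading_fraction=(0.0,),
                           unique_loading_fraction=(0.0,),
                           twin_fraction=0.0, seed=4)
    cohort = generate_cohort(cfg)
    summary = pd.DataFrame({"channel": ["channel0"], "median": [0.0],
                            "ci_low": [-0.1], "ci_high": [0.1]})
    results, skipped = refit_full(cohort.channels, cohort.response.values, summary)
    assert results == {} and skipped == ["channel0"]
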