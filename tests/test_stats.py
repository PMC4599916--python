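"""Distributional statistics: ECDF, 2D KDE modes, exceedance, permutation and rank tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucshift.exceptions import InputError
from nucshift.stats import (
    KdeSurface,
    count_modes,
    ecdf,
    exceedance_probability,
    kde2d,
    permutation_test,
    rank_test,
)

# ---------------------------------------------------------------------------
# ECDF


def test_ecdf_step_values():
    f = ecdf([1.0, 2.0, 3.0])
    assert f(2.0) == pytest.approx(2 / 3)
    assert f(0.5) == 0.0
    assert f(3.0) == 1.0


def test_ecdf_empty_input():
    with pytest.raises(InputError):
        ecdf([])


# ---------------------------------------------------------------------------
# KDE and mode counting


def test_kde_mode_count_unimodal_vs_bimodal(rng):
    one = rng.normal([0.3, 0.4], [0.04, 0.05], (2000, 2))
    s1 = kde2d(one[:, 0], one[:, 1])
    assert count_modes(s1) == 1
    two = np.vstack(
        [rng.normal([0.2, 0.3], [0.04, 0.04], (1000, 2)),
         rng.normal([0.5, 0.6], [0.04, 0.04], (1000, 2))]
    )
    s2 = kde2d(two[:, 0], two[:, 1])
    assert count_modes(s2) == 2
    assert s1.integral() == pytest.approx(1.0, abs=0.01)
    assert s2.integral() == pytest.approx(1.0, abs=0.01)
    assert np.all(s1.density >= 0)


def test_kde_matches_scipy_gaussian_kde(rng):
    # with independent axes scipy's Silverman covariance reduces to the same
    # per-axis bandwidths, so the two estimators must agree closely
    x = rng.normal(0.0, 1.0, 400)
    y = rng.normal(5.0, 2.0, 400)
    surf = kde2d(x, y, gridsize=32)
    from scipy.stats import gaussian_kde

    gx, gy = np.meshgrid(surf.x, surf.y, indexing="ij")
    ref = gaussian_kde(np.vstack([x, y]), bw_method="silverman")(
        np.vstack([gx.ravel(), gy.ravel()])
    ).reshape(gx.shape)
    assert np.max(np.abs(surf.density - ref)) <= 0.03 * ref.max()


def test_flat_surface_counts_one_plateau_mode():
    surf = KdeSurface(
        x=np.linspace(0, 1, 16), y=np.linspace(0, 1, 16),
        density=np.ones((16, 16)), bandwidth=(0.1, 0.1),
    )
    assert count_modes(surf) == 1


def test_full_prominence_keeps_only_global_max(rng):
    two = np.vstack(
        [rng.normal([0.2, 0.3], [0.03, 0.03], (1500, 2)),
         rng.normal([0.5, 0.6], [0.03, 0.03], (500, 2))]
    )
    surf = kde2d(two[:, 0], two[:, 1])
    assert count_modes(surf, prominence=0.1) == 2
    assert count_modes(surf, prominence=1.0) == 1


def test_mode_count_invariant_under_common_rescaling(rng):
    two = np.vstack(
        [rng.normal([0.2, 0.3], [0.04, 0.04], (800, 2)),
         rng.normal([0.5, 0.6], [0.04, 0.04], (800, 2))]
    )
    s = kde2d(two[:, 0], two[:, 1], bandwidth=(0.03, 0.03))
    k = 37.0
    sk = kde2d(k * two[:, 0], k * two[:, 1], bandwidth=(k * 0.03, k * 0.03))
    assert count_modes(s) == count_modes(sk) == 2


def test_kde_degenerate_axis_suggests_jitter():
    with pytest.raises(InputError, match="jitter"):
        kde2d(np.ones(50), np.arange(50, dtype=float))


def test_kde_requires_paired_samples_of_ten():
    with pytest.raises(InputError):
        kde2d(np.arange(5.0), np.arange(5.0))
    with pytest.raises(InputError):
        kde2d(np.arange(20.0), np.arange(19.0))


# ---------------------------------------------------------------------------
# exceedance probability


@pytest.mark.parametrize(
    "a, b, expected",
    [([2, 3], [1], 1.0), ([1], [1], 0.5), ([1, 3], [2], 0.5)],
)
def test_exceedance_examples(a, b, expected):
    assert exceedance_probability(a, b) == pytest.approx(expected)


@given(
    a=st.lists(st.integers(0, 5), min_size=1, max_size=30),
    b=st.lists(st.integers(0, 5), min_size=1, max_size=30),
)
def test_exceedance_tie_mass_splits_symmetrically(a, b):
    pa = exceedance_probability(a, b)
    pb = exceedance_probability(b, a)
    assert pa + pb == pytest.approx(1.0, abs=1e-12)
    # independent brute-force oracle
    pairs = [(x, y) for x in a for y in b]
    brute = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x, y in pairs) / len(pairs)
    assert pa == pytest.approx(brute, abs=1e-12)


def test_exceedance_empty_group_rejected():
    with pytest.raises(InputError):
        exceedance_probability([], [1.0])


# ---------------------------------------------------------------------------
# permutation test


def brute_force_permutation_p(a, b):
    """Independent oracle: enumerate every label assignment of the pooled sample."""
    pooled = list(a) + list(b)
    na, n = len(a), len(a) + len(b)
    t_obs = abs(np.mean(pooled[:na]) - np.mean(pooled[na:]))
    tol = 1e-9 * (1 + t_obs)
    count = total = 0
    for comb in itertools.combinations(range(n), na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(n) if i not in comb]
        total += 1
        if abs(np.mean(ga) - np.mean(gb)) >= t_obs - tol:
            count += 1
    return count / total


def test_exhaustive_worked_example():
    res = permutation_test([0, 0], [1, 1])
    assert res.mode == "exhaustive"
    assert res.n_iterations == 6
    assert res.p_value == pytest.approx(2 / 6)


def test_identical_multisets_give_p_one():
    res = permutation_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
    assert res.observed == 0.0
    assert res.p_value == 1.0


@pytest.mark.parametrize("na,nb", [(1, 1), (1, 3), (2, 2), (2, 4), (3, 3), (3, 5), (4, 4)])
def test_exhaustive_matches_brute_force_oracle(na, nb, rng):
    a = rng.integers(0, 4, na).astype(float)
    b = rng.integers(0, 4, nb).astype(float)
    res = permutation_test(a, b)
    assert res.mode == "exhaustive"
    assert res.p_value == brute_force_permutation_p(a, b)


def test_montecarlo_converges_to_exhaustive(rng):
    a = rng.normal(0.0, 1.0, 6)
    b = rng.normal(0.6, 1.0, 6)
    exact = permutation_test(a, b).p_value
    mc = permutation_test(a, b, n_iterations=10000, seed=5, exhaustive_cap=1)
    assert mc.mode == "montecarlo"
    se = math.sqrt(exact * (1 - exact) / 10000)
    assert abs(mc.p_value - exact) <= 2 * se + 1 / 10001


def test_permutation_input_validation():
    with pytest.raises(InputError):
        permutation_test([1.0], [2.0], n_iterations=0)
    with pytest.raises(InputError):
        permutation_test([], [1.0])
    with pytest.raises(InputError):
        permutation_test([1.0], [2.0], statistic="median_war")


def test_ks_statistic_variant_runs_exhaustively():
    res = permutation_test([0.0, 0.1], [1.0, 1.1], statistic="ks")
    assert res.statistic == "ks"
    assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------------
# rank test


def test_rank_test_extreme_ordering_exact():
    # most extreme split of 6 ranks: two-sided p = 2/20
    assert rank_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_rank_test_identical_groups():
    assert rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)


def test_rank_test_all_tied_warns():
    with pytest.warns(UserWarning, match="tied"):
        assert rank_test([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0


def test_rank_test_power_under_clear_shift(rng):
    # n = 1000/group, shift of 0.5 pooled sd: essentially certain detection
    for _ in range(20):
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(0.5, 1.0, 1000)
        assert rank_test(a, b) < 1e-3
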