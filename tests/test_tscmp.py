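"""Smoothing, banded DTW and the Δ_RMSD / f comparison statistics."""

import functools
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phstab.tscmp import (
    AlignmentPath,
    TSCompareConfig,
    compare_models,
    delta_and_f,
    dtw_align,
    smooth_moving_average,
    window_sensitivity,
)


# ---------------------------------------------------------------------------
# independent DTW oracles
# ---------------------------------------------------------------------------

def oracle_min_cost(a, b, window):
    """Top-down Bellman recursion, memoized; independent of the banded DP."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if window > 0 and abs(i - j) > window:
            return np.inf
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        options = []
        if i > 0 and j > 0:
            options.append(rec(i - 1, j - 1))
        if i > 0:
            options.append(rec(i - 1, j))
        if j > 0:
            options.append(rec(i, j - 1))
        return c + min(options)

    return rec(len(a) - 1, len(b) - 1)


def oracle_enumerate_paths(a, b, window):
    """True exhaustive enumeration of every admissible monotone path."""
    n, m = len(a), len(b)
    best = np.inf

    def walk(i, j, cost):
        nonlocal best
        cost += abs(a[i] - b[j])
        if cost >= best:
            return
        if i == n - 1 and j == m - 1:
            best = min(best, cost)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m and (window == 0 or abs(ni - nj) <= window):
                walk(ni, nj, cost)

    walk(0, 0, 0.0)
    return best


def _assert_valid_path(path: AlignmentPath, n, m):
    pairs = path.pairs
    assert pairs[0] == (0, 0) and pairs[-1] == (n - 1, m - 1)
    for (i0, j0), (i1, j1) in itertools.pairwise(pairs):
        assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}
    if path.window > 0:
        assert all(abs(i - j) <= path.window for i, j in pairs)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smoothing_examples():
    np.testing.assert_allclose(
        smooth_moving_average([1, 2, 3, 4, 5], 3), [1.5, 2, 3, 4, 4.5]
    )
    constant = np.full(20, 2.5)
    np.testing.assert_allclose(smooth_moving_average(constant, 10), constant)
    x = np.arange(7.0)
    np.testing.assert_allclose(smooth_moving_average(x, 1), x)


def test_smoothing_preserves_length_and_interior_mean(rng):
    x = rng.normal(size=100)
    for w in (3, 10, 11):
        sm = smooth_moving_average(x, w)
        assert sm.shape == x.shape
        # away from the edges the window is complete: exact centered mean
        k = 50
        left = (w - 1 + 1) // 2
        right = (w - 1) // 2
        assert sm[k] == pytest.approx(np.mean(x[k - left : k + right + 1]))


def test_smoothing_rejects_empty_series():
    with pytest.raises(ValueError):
        smooth_moving_average([], 3)


# ---------------------------------------------------------------------------
# DTW alignment
# ---------------------------------------------------------------------------

def test_identical_series_align_on_the_diagonal():
    x = np.array([0.3, 0.5, 0.9, 0.2])
    for w in (0, 1, 3):
        path = dtw_align(x, x, w)
        assert path.pairs == [(i, i) for i in range(4)]
        assert path.total_cost == 0.0


def test_window_zero_is_identity_pairing():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([1.5, 2.5, 3.5])
    path = dtw_align(a, b, 0)
    assert path.pairs == [(0, 0), (1, 1), (2, 2)]
    assert path.total_cost == pytest.approx(1.5)
    with pytest.raises(ValueError):
        dtw_align(a, b[:2], 0)


def test_small_alignment_matches_exhaustive_enumeration():
    a = [0.0, 0.0, 1.0]
    b = [0.0, 1.0, 1.0]
    path = dtw_align(a, b, 2)
    assert path.total_cost == pytest.approx(oracle_enumerate_paths(a, b, 2))
    _assert_valid_path(path, 3, 3)


def test_dtw_cost_matches_memoized_oracle_on_random_pairs(rng):
    for _ in range(30):
        n = int(rng.integers(2, 21))
        m = int(rng.integers(max(2, n - 5), n + 6))
        a = rng.uniform(0, 3, size=n)
        b = rng.uniform(0, 3, size=m)
        for w in (max(abs(n - m), 1), 5, 20):
            path = dtw_align(a, b, w)
            _assert_valid_path(path, n, m)
            assert path.total_cost == pytest.approx(
                oracle_min_cost(tuple(a), tuple(b), w)
            )
            # the reported path realizes the reported cost
            realized = sum(abs(a[i] - b[j]) for i, j in path.pairs)
            assert realized == pytest.approx(path.total_cost)


def test_dtw_cost_nonincreasing_in_window(rng):
    a = rng.uniform(0, 2, size=30)
    b = rng.uniform(0, 2, size=30)
    costs = [dtw_align(a, b, w).total_cost for w in (1, 2, 5, 10, 29)]
    assert all(c1 >= c2 - 1e-12 for c1, c2 in itertools.pairwise(costs))


def test_dtw_traceback_deterministic():
    a = np.array([1.0, 1.0, 1.0, 1.0])
    b = np.array([1.0, 1.0, 1.0, 1.0])
    p1 = dtw_align(a, b, 3)
    p2 = dtw_align(a, b, 3)
    assert p1.pairs == p2.pairs == [(i, i) for i in range(4)]  # diagonal preferred


# ---------------------------------------------------------------------------
# delta / f
# ---------------------------------------------------------------------------

def test_self_comparison_gives_zero_delta_unit_f(rng):
    x = rng.uniform(0.5, 2.0, size=40)
    path = dtw_align(x, x, 5)
    delta, f = delta_and_f(x, x, path)
    assert delta == 0.0 and f == 1.0


def test_constant_offset_pair():
    a = np.full(25, 1.0)
    b = np.full(25, 2.0)
    path = dtw_align(a, b, 0)
    delta, f = delta_and_f(a, b, path)
    assert delta == pytest.approx(1.0) and f == 0.0
    delta_r, f_r = delta_and_f(b, a, dtw_align(b, a, 0))
    assert delta_r == pytest.approx(-1.0) and f_r == 1.0


def test_delta_f_match_per_element_recomputation(rng):
    a = rng.uniform(0, 2, size=15)
    b = rng.uniform(0, 2, size=15)
    path = dtw_align(a, b, 4)
    delta, f = delta_and_f(a, b, path)
    diffs = [b[j] - a[i] for i, j in path.pairs]
    assert delta == pytest.approx(np.mean(diffs))
    assert f == pytest.approx(np.mean([a[i] >= b[j] for i, j in path.pairs]))


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(min_value=0, max_value=5), min_size=2, max_size=25))
def test_window0_antisymmetry(values):
    a = np.asarray(values)
    b = a[::-1].copy()
    pa = dtw_align(a, b, 0)
    pb = dtw_align(b, a, 0)
    da, fa = delta_and_f(a, b, pa)
    db, fb = delta_and_f(b, a, pb)
    assert da == pytest.approx(-db, abs=1e-12)
    assert fa + fb >= 1.0  # equality iff no ties


# ---------------------------------------------------------------------------
# replicate-set comparison
# ---------------------------------------------------------------------------

SMALL_CFG = TSCompareConfig(
    ma_window=3, dtw_windows=(0, 5, 10), report_window=5, expected_length=50
)


def test_identical_sets_compare_trivially(rng):
    series = [rng.uniform(0.5, 2.0, size=50) for _ in range(3)]
    result = compare_models(series, series, SMALL_CFG)
    assert result.delta_rmsd == pytest.approx(0.0, abs=1e-12)
    # ordered self-pairs are identical; cross pairs need not be, but the
    # diagonal forces f's mean above the cross-pair value
    assert result.n_pairwise == 9


def test_constant_sets_give_exact_offset():
    set1 = [np.full(40, 1.0)] * 3
    set2 = [np.full(40, 1.5)] * 3
    result = compare_models(set1, set2, SMALL_CFG)
    assert result.delta_rmsd == pytest.approx(0.5)
    assert result.delta_sd == 0.0
    assert result.f == 0.0
    assert result.rmsd1_mean == pytest.approx(1.0)
    assert result.rmsd2_mean == pytest.approx(1.5)


def test_exact_self_set_is_delta_zero_f_one(rng):
    s = rng.uniform(0.5, 2.0, size=50)
    result = compare_models([s], [s], SMALL_CFG)
    assert result.delta_rmsd == 0.0 and result.f == 1.0


def test_series_trimmed_to_expected_length(rng):
    long = np.concatenate([np.full(30, 9.0), np.full(50, 1.0)])
    short = np.full(50, 1.0)
    result = compare_models([long], [short], SMALL_CFG, window=5)
    # only the trailing 50 frames are compared, so the early 9.0 block is ignored
    assert result.delta_rmsd == pytest.approx(0.0, abs=1e-12)


def test_window_sensitivity_rows(rng):
    x = rng.uniform(0.5, 2.0, size=50)
    rows = window_sensitivity(x, x, SMALL_CFG)
    assert [r.window for r in rows] == [0, 5, 10]
    assert all(r.delta_rmsd == 0.0 and r.f == 1.0 for r in rows)
    rows_off = window_sensitivity(np.full(50, 1.0), np.full(50, 1.8), SMALL_CFG)
    assert all(r.delta_rmsd == pytest.approx(0.8) for r in rows_off)


def test_no_dtw_delta_at_least_as_large_as_windowed(rng):
    # genuinely offset, out-of-phase series: warping matches similar levels
    # and shrinks |delta| relative to the frame-by-frame comparison
    t = np.arange(200)
    a = 1.0 + 0.2 * np.sin(t / 8) + rng.normal(0, 0.03, 200)
    b = 1.0 + 0.5 * t / 200 + 0.2 * np.sin((t - 12) / 8) + rng.normal(0, 0.03, 200)
    cfg = TSCompareConfig(ma_window=5, dtw_windows=(0, 50), report_window=50, expected_length=200)
    no_dtw = compare_models([a], [b], cfg, window=0)
    with_dtw = compare_models([a], [b], cfg, window=50)
    assert abs(no_dtw.delta_rmsd) >= abs(with_dtw.delta_rmsd) - 1e-9


def test_config_validation():
    with pytest.raises(ValueError):
        TSCompareConfig(ma_window=0)
    with pytest.raises(ValueError):
        TSCompareConfig(report_window=123)
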