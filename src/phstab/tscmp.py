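"""Trajectory comparison by dynamic time warping of RMSD series.

Two MD trajectories of the same system under different conditions are
compared through their per-frame RMSD series: each series is smoothed by a
10-frame moving average, the two series are aligned by dynamic time warping
(DTW) under a Sakoe–Chiba band constraint |i − j| ≤ window, and two
statistics are read off the alignment:

* ``Δ_RMSD`` — the mean over aligned element pairs of RMSD₂ − RMSD₁
  (signed; its sign depends on the argument order), and
* ``f`` — the fraction of aligned pairs with RMSD₁ ≥ RMSD₂ (non-strict).

A low ``f`` (≲ 0.05) means series 2 lies above series 1 almost everywhere
after optimal time-shifting, i.e. the second model is systematically more
deviated — a significant destabilization signal.  Replicate sets are
compared over all ordered pairwise combinations (3 × 3 = 9 for triplicate
runs) and summarised as mean ± sample SD.

The DP uses unit-weight steps {(1,0), (0,1), (1,1)}, local cost |aᵢ − bⱼ|,
fixed endpoints, and a deterministic traceback (diagonal preferred, then
the step consuming series 1).  Window 0 means no DTW: the identity pairing
of equal-length series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

from .structio import RMSDSeries

__all__ = [
    "TSCompareConfig",
    "AlignmentPath",
    "ComparisonResult",
    "smooth_moving_average",
    "dtw_align",
    "delta_and_f",
    "compare_models",
    "window_sensitivity",
]

#: f at or below this is flagged as a significant (de)stabilization.
DEFAULT_SIGNIFICANCE_F = 0.05


@dataclass(frozen=True)
class TSCompareConfig:
    """Parameters of the RMSD-series comparison protocol."""

    ma_window: int = 10
    dtw_windows: tuple[int, ...] = (0, 100, 250, 500, 750, 900, 1000)
    report_window: int = 500
    expected_length: int = 2000
    significance_f: float = DEFAULT_SIGNIFICANCE_F

    def __post_init__(self) -> None:
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if any(w < 0 for w in self.dtw_windows):
            raise ValueError("DTW windows must be >= 0")
        if self.report_window not in self.dtw_windows:
            raise ValueError("report_window must be one of dtw_windows")


@dataclass
class AlignmentPath:
    """Monotone DTW path: ordered (i, j) index pairs, 0-based.

    Starts at (0, 0), ends at (n−1, m−1); steps are (1,0), (0,1) or (1,1);
    |i − j| ≤ window for every pair when window > 0; window 0 yields the
    identity pairing.
    """

    pairs: list[tuple[int, int]]
    window: int
    total_cost: float

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class ComparisonResult:
    """Δ_RMSD and f for one pair or one replicate-set cross-comparison."""

    delta_rmsd: float
    delta_sd: float
    f: float
    window: int
    n_pairwise: int
    rmsd1_mean: float = float("nan")
    rmsd1_sd: float = float("nan")
    rmsd2_mean: float = float("nan")
    rmsd2_sd: float = float("nan")
    significance_f: float = DEFAULT_SIGNIFICANCE_F

    @property
    def significant(self) -> bool:
        return self.f <= self.significance_f

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f outside [0, 1]: {self.f}")


def _as_values(series) -> np.ndarray:
    if isinstance(series, RMSDSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def smooth_moving_average(series, window: int = 10) -> np.ndarray:
    """Centered moving average, truncated at the edges; length-preserving.

    For even windows the extra element goes to the left (window w covers
    indices k−⌈(w−1)/2⌉ … k+⌊(w−1)/2⌋, clipped to the series).
    """
    x = _as_values(series)
    if x.size == 0:
        raise ValueError("empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return x.copy()
    n = x.size
    left = (window - 1 + 1) // 2  # ceil((w-1)/2)
    right = (window - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    k = np.arange(n)
    lo = np.maximum(0, k - left)
    hi = np.minimum(n, k + right + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


@njit(cache=True)
def _dtw_matrix(a: np.ndarray, b: np.ndarray, window: int) -> np.ndarray:  # pragma: no cover
    n, m = a.size, b.size
    inf = np.inf
    d = np.full((n, m), inf)
    for i in range(n):
        jlo = max(0, i - window)
        jhi = min(m - 1, i + window)
        for j in range(jlo, jhi + 1):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                d[0, 0] = c
                continue
            best = inf
            if i > 0 and j > 0 and d[i - 1, j - 1] < best:
                best = d[i - 1, j - 1]
            if i > 0 and d[i - 1, j] < best:
                best = d[i - 1, j]
            if j > 0 and d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = c + best
    return d


def dtw_align(series_a, series_b, window: int) -> AlignmentPath:
    """Optimal banded DTW alignment of two scalar series.

    Window 0 disables warping and requires equal lengths (identity pairing).
    Ties in the traceback are broken deterministically: diagonal first, then
    the step advancing series a.
    """
    a = _as_values(series_a)
    b = _as_values(series_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty series")
    n, m = a.size, b.size
    if window == 0:
        if n != m:
            raise ValueError("window 0 (no DTW) requires equal-length series")
        pairs = [(i, i) for i in range(n)]
        cost = float(np.sum(np.abs(a - b)))
        return AlignmentPath(pairs=pairs, window=0, total_cost=cost)
    if abs(n - m) > window:
        raise ValueError(
            f"band of width {window} cannot join series of lengths {n} and {m}"
        )
    d = _dtw_matrix(a, b, int(window))
    # traceback: prefer diagonal, then advance-a ((i-1, j)), then advance-b
    pairs = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while i > 0 or j > 0:
        cands = []
        if i > 0 and j > 0:
            cands.append((d[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            cands.append((d[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            cands.append((d[i, j - 1], 2, (i, j - 1)))
        cands = [c for c in cands if np.isfinite(c[0])]
        cands.sort(key=lambda c: (c[0], c[1]))
        i, j = cands[0][2]
        pairs.append((i, j))
    pairs.reverse()
    return AlignmentPath(pairs=pairs, window=int(window), total_cost=float(d[n - 1, m - 1]))


def delta_and_f(series_a, series_b, path: AlignmentPath) -> tuple[float, float]:
    """Δ_RMSD and f over an alignment path.

    Δ_RMSD = mean over path elements of (b_j − a_i); positive when series b
    runs above series a.  f = fraction of path elements with a_i ≥ b_j
    (non-strict, so self-comparison gives f = 1).
    """
    a = _as_values(series_a)
    b = _as_values(series_b)
    if len(path) == 0:
        raise ValueError("empty alignment path")
    ii = np.fromiter((p[0] for p in path.pairs), dtype=int, count=len(path))
    jj = np.fromiter((p[1] for p in path.pairs), dtype=int, count=len(path))
    diffs = b[jj] - a[ii]
    delta = float(np.mean(diffs))
    f = float(np.mean(a[ii] >= b[jj]))
    return delta, f


def _prepare(series, config: TSCompareConfig) -> np.ndarray:
    x = _as_values(series)
    if config.expected_length and x.size > config.expected_length:
        x = x[-config.expected_length :]
    return smooth_moving_average(x, config.ma_window)


def compare_models(
    series_set_1: Sequence,
    series_set_2: Sequence,
    config: TSCompareConfig = TSCompareConfig(),
    window: int | None = None,
) -> ComparisonResult:
    """Cross-compare two replicate sets of RMSD series.

    Every ordered pair (s₁ from set 1 as MD1, s₂ from set 2 as MD2) is
    smoothed, DTW-aligned at ``window`` (default: the config's report
    window) and scored; Δ_RMSD is reported as mean ± sample SD over the
    pairs and f as the mean.  Set-level RMSD summaries (mean ± sample SD of
    the per-replicate series means) are attached for reporting.
    """
    if window is None:
        window = config.report_window
    if not series_set_1 or not series_set_2:
        raise ValueError("each set must contain >= 1 series")
    prep1 = [_prepare(s, config) for s in series_set_1]
    prep2 = [_prepare(s, config) for s in series_set_2]
    deltas, fs = [], []
    for s1 in prep1:
        for s2 in prep2:
            path = dtw_align(s1, s2, window)
            delta, f = delta_and_f(s1, s2, path)
            deltas.append(delta)
            fs.append(f)
    deltas = np.asarray(deltas)
    fs = np.asarray(fs)

    def _mean_sd(values: np.ndarray) -> tuple[float, float]:
        sd = float(values.std(ddof=1)) if values.size >= 2 else 0.0
        return float(values.mean()), sd

    m1 = np.asarray([s.mean() for s in prep1])
    m2 = np.asarray([s.mean() for s in prep2])
    r1_mean, r1_sd = _mean_sd(m1)
    r2_mean, r2_sd = _mean_sd(m2)
    d_mean, d_sd = _mean_sd(deltas)
    return ComparisonResult(
        delta_rmsd=d_mean,
        delta_sd=d_sd,
        f=float(fs.mean()),
        window=int(window),
        n_pairwise=len(deltas),
        rmsd1_mean=r1_mean,
        rmsd1_sd=r1_sd,
        rmsd2_mean=r2_mean,
        rmsd2_sd=r2_sd,
        significance_f=config.significance_f,
    )


def window_sensitivity(
    series_a,
    series_b,
    config: TSCompareConfig = TSCompareConfig(),
) -> list[ComparisonResult]:
    """Δ_RMSD and f for one series pair at every configured DTW window."""
    out = []
    for w in config.dtw_windows:
        try:
            out.append(compare_models([series_a], [series_b], config, window=w))
        except ValueError:
            # window 0 with unequal lengths: skip that row
            continue
    return out
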