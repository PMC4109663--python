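"""Summary statistics and tests used by the protocol evaluation.

Percentiles use the Hazen convention — linear interpolation between order
statistics at probability points (k − 0.5)/n, clamped at the extremes — the
convention that reproduces the published quartile ranges.  The Wilcoxon
signed-rank test is exact (full null distribution) up to n = 25 paired
differences, with zero differences dropped and average ranks for ties; a
tie-corrected normal approximation is used beyond that.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy
from scipy.stats import norm, rankdata

__all__ = ["percentile", "median", "wilcoxon_paired", "wolpaw_bits_per_selection", "wolpaw_bitrate"]


def percentile(values, q: float) -> float:
    """Hazen percentile (q in [0, 100])."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of empty input")
    return float(np.percentile(values, q, method="hazen"))


def median(values) -> float:
    return percentile(values, 50.0)


def _exact_sf_cdf(weights: np.ndarray, w2: int):
    """CDF/SF of 2·W+ under the signed-rank null via dynamic programming.

    ``weights`` are the doubled ranks (integers even with average-rank ties).
    Returns (P(2W+ <= w2), P(2W+ >= w2)).
    """
    total = int(weights.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for w in weights:
        new = counts.copy()
        new[w:] += counts[: total + 1 - w]
        counts = new
    counts /= counts.sum()
    return float(counts[: w2 + 1].sum()), float(counts[w2:].sum())


def wilcoxon_paired(x, y):
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Returns ``(statistic, p_value)`` with statistic = min(W+, W−).  Zero
    differences are dropped; tied absolute differences get average ranks.
    Exact null distribution for n ≤ 25 (p = min(1, 2·P(W ≤ w_obs))),
    tie-corrected normal approximation otherwise.  All-zero differences give
    the degenerate p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.ndim != 1:
        raise ValueError("paired samples must be 1-D")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= 25:
        weights = np.rint(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * stat))
        cdf, _ = _exact_sf_cdf(weights, w2)
        p = min(1.0, 2.0 * cdf)
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        se = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (stat - mu + 0.5) / se  # continuity-corrected toward the mean
        p = min(1.0, 2.0 * norm.cdf(z))
    return stat, float(p)


def wolpaw_bits_per_selection(accuracy_p: float, n_choices: int) -> float:
    """Wolpaw information per selection (bits).

    B = log2 N + P log2 P + (1−P) log2((1−P)/(N−1)), with the P→0 and P→1
    limits taken by continuity.
    """
    P = float(accuracy_p)
    N = int(n_choices)
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if N < 2:
        raise ValueError("n_choices must be >= 2")
    log2 = np.log(2.0)
    b = (
        np.log2(N)
        + xlogy(P, P) / log2
        + xlogy(1.0 - P, (1.0 - P) / (N - 1)) / log2
    )
    return float(b)


def wolpaw_bitrate(accuracy_p: float, n_choices: int, seconds_per_selection: float) -> float:
    """Wolpaw information transfer rate in bit/min."""
    if seconds_per_selection <= 0:
        raise ValueError("seconds_per_selection must be positive")
    return wolpaw_bits_per_selection(accuracy_p, n_choices) * 60.0 / seconds_per_selection
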