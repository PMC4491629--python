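"""Bootstrap summaries and condition comparisons.

Non-gaussian population summaries are reported as the sample mean spanning
the 25th-75th percentile confidence interval of 100,000 bootstrap resamples
of the mean. Two-group comparisons ("bootstrapped confidence assessment",
p_bca) use the two-sided sign-fraction of the bootstrap distribution of the
mean difference.
"""

from __future__ import annotations

import numpy as np

DEFAULT_N_BOOT = 100_000

_CHUNK = 20_000_000  # max resampled values per block, bounds memory


def _bootstrap_means(values: np.ndarray, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    n = values.size
    means = np.empty(n_boot)
    rows_per_block = max(1, _CHUNK // n)
    start = 0
    while start < n_boot:
        stop = min(start + rows_per_block, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        means[start:stop] = values[idx].mean(axis=1)
        start = stop
    return means


def bootstrap_mean_ci(values, n_boot: int = DEFAULT_N_BOOT,
                      quantiles=(0.25, 0.75), seed: int | None = 0):
    """Return (mean, ci_low, ci_high): sample mean and the stated quantiles
    of the bootstrap distribution of the mean. Deterministic under seed."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    means = _bootstrap_means(v, n_boot, rng)
    lo, hi = np.quantile(means, quantiles)
    return float(v.mean()), float(lo), float(hi)


def bootstrap_compare(group_a, group_b, n_boot: int = DEFAULT_N_BOOT,
                      seed: int | None = 0) -> float:
    """Two-sided bootstrap p-value for a difference in group means.

    p = 2 x min(P(diff* <= 0), P(diff* >= 0)) over bootstrap resamples of
    each group, clipped to [1/n_boot, 1]. Symmetric in group order.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    # assign each group its random stream by a canonical (data-based) order
    # so that swapping the argument order cannot change the p-value
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    if (a.tobytes(), a.size) <= (b.tobytes(), b.size):
        first, second, sign = a, b, 1.0
    else:
        first, second, sign = b, a, -1.0
    diffs = sign * (_bootstrap_means(first, n_boot, np.random.default_rng(s1))
                    - _bootstrap_means(second, n_boot, np.random.default_rng(s2)))
    p_low = np.mean(diffs <= 0)
    p_high = np.mean(diffs >= 0)
    p = 2.0 * min(p_low, p_high)
    return float(np.clip(p, 1.0 / n_boot, 1.0))
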