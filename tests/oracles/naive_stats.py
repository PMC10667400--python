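"""Brute-force statistical oracles: two-way ANOVA ICC and BH step-up."""

from __future__ import annotations

import numpy as np


def icc_2_1_bruteforce(data: np.ndarray) -> float:
    """ICC(2,1) from explicitly accumulated sums of squares."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = sum(data[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssr = sum(k * (sum(data[i]) / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (sum(data[:, j]) / n - grand) ** 2 for j in range(k))
    sst = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return (msr - mse) / denom


def bh_bruteforce(p_values) -> np.ndarray:
    """BH step-up: adj_i = min_{j >= i} m p_(j) / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted
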