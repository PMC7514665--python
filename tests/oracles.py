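"""Independent brute-force reference implementations used only by tests.

These deliberately use naive Python loops and scipy.stats so that they share
no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def sampen_bruteforce(x, m: int, tol: float) -> float:
    """O(N^2) pair-counting sample entropy, Richman-Moorman convention.

    Templates i = 0..N-m-1 for both lengths m and m+1; Chebyshev distance;
    self-matches excluded; returns -ln(A/B) with the same degenerate-count
    conventions as the package (B=0 -> NaN, A=0 -> ln(B))."""
    x = list(map(float, x))
    n = len(x)
    n_templates = n - m

    def count(length: int) -> int:
        c = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if d <= tol:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0:
        return math.nan
    if a == 0:
        return math.log(b)
    return -math.log(a / b)


def lag_scan_pearson(x: np.ndarray, y: np.ndarray, max_lag: int):
    """Brute-force all-lag Pearson scan via scipy.stats.pearsonr.

    Positive lag means x is delayed by ``lag`` steps relative to y. Returns
    (best correlation, best lag)."""
    n = len(x)
    best = (-np.inf, 0)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = x[lag:], y[: n - lag]
        else:
            a, b = x[: n + lag], y[-lag:]
        if len(a) < 10:
            continue
        r = stats.pearsonr(a, b).statistic
        if r > best[0]:
            best = (float(r), lag)
    return best
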