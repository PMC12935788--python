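"""Independent brute-force oracles for the correlation machinery.

These deliberately use naive loops and textbook formulas, sharing no
code with the package implementation.
"""

import math

import numpy as np


def pearson_pairs(xs, ys):
    """Textbook Pearson correlation over paired samples."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def brute_cross_correlation(a, b, mask_a, mask_b, lag):
    """Pairwise-deleted correlation of a(t) with b(t+lag), naive loop."""
    xs, ys = [], []
    for t in range(len(a)):
        u = t + lag
        if 0 <= u < len(b) and mask_a[t] and mask_b[u]:
            xs.append(float(a[t]))
            ys.append(float(b[u]))
    return pearson_pairs(xs, ys), len(xs)


def brute_delay_matrix(series, masks, n_delays, step):
    """Entry-by-entry construction of the channel-delay matrix."""
    n = len(series)
    size = n * n_delays
    M = np.empty((size, size))
    for i in range(n):
        for j in range(n):
            for a in range(n_delays):
                for b in range(n_delays):
                    lag = (b - a) * step
                    r, _ = brute_cross_correlation(
                        series[i], series[j], masks[i], masks[j], lag
                    )
                    M[i * n_delays + a, j * n_delays + b] = r
    return 0.5 * (M + M.T)
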