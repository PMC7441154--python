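"""Independent brute-force oracles shared across test modules."""

import math

from scipy import stats


def brute_force_mann_kendall(series):
    """All-pairs Mann-Kendall statistic computed the slow, obvious way."""
    x = list(series)
    n = len(x)
    s = 0
    for a in range(n - 1):
        for b in range(a + 1, n):
            diff = x[b] - x[a]
            s += (diff > 0) - (diff < 0)
    counts = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in counts.values() if t > 1)
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var_s)
    else:
        z = (s + 1) / math.sqrt(var_s)
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return s, var_s, p


def random_tied_series(generator, n):
    """Short series drawn from a small value set so ties are common."""
    return [float(v) for v in generator.integers(0, 4, size=n)]
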