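"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (definitions, expanded
per-case records, rank formulas) and deliberately shares no code with the
package internals it checks.
"""

from __future__ import annotations

import math
from collections import defaultdict

from scipy.stats import chi2


def percentile_oracle(values, p, method):
    """Order-statistic interpolation from its textbook definition.

    ``weibull``: rank h = (n+1) * p/100; ``linear``: h = (n-1) * p/100 + 1.
    Linear interpolation between the floor and ceiling order statistics,
    clamped to the sample extremes.
    """
    xs = sorted(float(v) for v in values)
    n = len(xs)
    q = p / 100.0
    h = (n + 1) * q if method == "weibull" else (n - 1) * q + 1
    if h <= 1:
        return xs[0]
    if h >= n:
        return xs[-1]
    k = math.floor(h)
    frac = h - k
    return xs[k - 1] + frac * (xs[k] - xs[k - 1])


def kruskal_oracle(groups):
    """Tie-corrected Kruskal-Wallis H via explicit average ranks."""
    pooled = [(v, gi) for gi, g in enumerate(groups) for v in g]
    n = len(pooled)
    by_value = defaultdict(list)
    for idx, v in enumerate(sorted(v for v, _ in pooled)):
        by_value[v].append(idx + 1)
    ranks = {v: sum(r) / len(r) for v, r in by_value.items()}
    rank_sums = defaultdict(float)
    counts = defaultdict(int)
    for v, gi in pooled:
        rank_sums[gi] += ranks[v]
        counts[gi] += 1
    h = 12.0 / (n * (n + 1)) * sum(
        rank_sums[gi] ** 2 / counts[gi] for gi in counts
    ) - 3 * (n + 1)
    tie_sizes = [len(r) for r in by_value.values()]
    correction = 1 - sum(t**3 - t for t in tie_sizes) / (n**3 - n)
    if correction == 0:
        return None
    h /= correction
    p = float(chi2.sf(h, len(groups) - 1))
    return h, p


def merge_pooled_oracle(per_insurer_rows):
    """Pool insurer tables by expanding to one record per hospital case.

    ``per_insurer_rows``: list of (icd3, cases, mean_cost) across insurers.
    Returns {icd3: (cases, mean_cost)} recomputed from the expansion.
    """
    costs = defaultdict(list)
    for icd3, cases, mean_cost in per_insurer_rows:
        costs[icd3].extend([mean_cost] * cases)
    return {
        code: (len(cs), sum(cs) / len(cs)) for code, cs in costs.items() if cs
    }
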