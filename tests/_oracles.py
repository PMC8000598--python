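"""Independent brute-force oracles used to cross-check the statistics.

Each oracle re-derives its quantity from the definition (ranks + Pearson,
ECDF sup scan, per-interval tally, windowed means) without touching the
implementation it checks.
"""

import numpy as np


def rank_average_ties(values):
    """1-based average ranks computed by explicit tie-group scanning."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    return ranks


def spearman_bruteforce(a, b):
    """Rank both vectors, then Pearson correlation of the ranks."""
    ra = rank_average_ties(a)
    rb = rank_average_ties(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


def ks_bruteforce(a, b):
    """Sup over every observed threshold of the ECDF difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        best = max(best, abs((a <= t).mean() - (b <= t).mean()))
    return best


def count_ends_bruteforce(intervals, genome_length):
    """Per-position 5'-end tally by looping over intervals."""
    plus = np.zeros(genome_length, dtype=int)
    minus = np.zeros(genome_length, dtype=int)
    for iv in intervals:
        if iv.strand == "+":
            plus[iv.start] += 1
        else:
            minus[iv.end - 1] += 1
    return plus, minus


def moving_average_bruteforce(values, window):
    """Windowed means via an explicit slice per output position."""
    v = np.asarray(values, dtype=float)
    return np.array([v[i : i + window].mean() for i in range(len(v) - window + 1)])
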