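"""Independent scalar-loop oracles used to cross-check the implementation.

Everything here is written deliberately as plain Python loops over the
textbook definitions, sharing no code with the package internals.
"""
import itertools
import math


def mi_scalar(table):
    """Plug-in mutual information of a count table, in bits (scalar loops)."""
    n = sum(sum(row) for row in table)
    rows = [sum(row) for row in table]
    cols = [sum(row[j] for row in table) for j in range(len(table[0]))]
    total = 0.0
    for i, row in enumerate(table):
        for j, c in enumerate(row):
            if c > 0:
                p = c / n
                total += p * math.log2(p * n * n / (rows[i] * cols[j]))
    return total


def _bin_index(value, cuts):
    return sum(value > c for c in cuts)


def _counts(x, y, xcuts, ycuts):
    table = [[0] * (len(ycuts) + 1) for _ in range(len(xcuts) + 1)]
    for xi, yi in zip(x, y):
        table[_bin_index(xi, xcuts)][_bin_index(yi, ycuts)] += 1
    return table


def _midpoints(values):
    u = sorted(set(values))
    return [(a + b) / 2 for a, b in zip(u, u[1:])]


def max_grid_mi_bruteforce(x, y, x_bins, y_bins):
    """Exhaustive max mutual information over every (x_bins, y_bins) grid."""
    xc, yc = _midpoints(x), _midpoints(y)
    xb = min(x_bins, len(xc) + 1)
    yb = min(y_bins, len(yc) + 1)
    if xb < 2 or yb < 2:
        return 0.0
    best = 0.0
    for xs in itertools.combinations(xc, xb - 1):
        for ys in itertools.combinations(yc, yb - 1):
            best = max(best, mi_scalar(_counts(x, y, xs, ys)))
    return best


def mic_bruteforce(x, y, exponent=0.8):
    """Exhaustive MIC over every cut-point subset on both axes."""
    n = len(x)
    bound = n ** exponent
    xc, yc = _midpoints(x), _midpoints(y)
    best = 0.0
    for xb in range(2, len(xc) + 2):
        for yb in range(2, len(yc) + 2):
            if xb * yb >= bound:
                continue
            value = max_grid_mi_bruteforce(x, y, xb, yb)
            best = max(best, value / math.log2(min(xb, yb)))
    return best
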