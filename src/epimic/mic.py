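"""Maximal information coefficient (MIC) for finite bivariate samples.

MIC scores the association between two variables as the maximum, over
axis-aligned grids, of the grid's mutual information normalised by
``log2(min(x_bins, y_bins))``.  The grid search is restricted to grids with
``x_bins * y_bins < B(n) = n ** exponent``; the default exponent here is 0.8,
which is effective for genotype data.  MIC lies in [0, 1], is symmetric, and
is invariant under strictly increasing relabelling of either axis.

For small alphabets (at most :data:`EXACT_ALPHABET` distinct values per axis
— every genotype vector qualifies) the optimiser enumerates *all* cut-point
placements, so the returned score is the exact MIC.  Richer or continuous
variables are searched over a bounded pool of rank-equipartition candidate
cut points; that path is an approximation and sits outside the epistasis
workflow.

All mutual-information values are in bits (base-2 logarithms).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "DEFAULT_EXPONENT",
    "EXACT_ALPHABET",
    "GridBoundError",
    "CharacteristicMatrix",
    "MicResult",
    "contingency_counts",
    "mutual_information",
    "max_grid_mi",
    "characteristic_matrix",
    "mic",
    "mic_counts_3x3",
]

DEFAULT_EXPONENT = 0.8
EXACT_ALPHABET = 6
_CANDIDATE_POOL = 12  # rank-equipartition candidate cuts beyond EXACT_ALPHABET


class GridBoundError(ValueError):
    """The grid bound B(n) admits no 2x2 grid (B(n) <= 4)."""


@dataclass(frozen=True)
class MicResult:
    """MIC score together with the grid dimensions attaining it."""

    mic: float
    best_x_bins: int
    best_y_bins: int
    grid_bound: float
    exponent: float


@dataclass(frozen=True)
class CharacteristicMatrix:
    """Normalised maximised mutual information indexed by grid dimensions.

    ``entries[(x_bins, y_bins)]`` holds ``I*(D, x, y) / log2(min(x, y))`` for
    every populated grid size; only sizes with ``x_bins * y_bins <
    grid_bound`` (and within the feasible alphabet of each axis) appear.
    """

    entries: dict
    grid_bound: float
    n: int
    exponent: float

    def max_entry(self):
        """Return ``((x_bins, y_bins), value)`` of the largest entry."""
        key = max(self.entries, key=lambda k: self.entries[k])
        return key, self.entries[key]


def _validate_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed; pre-filter or impute")
    return x, y


def contingency_counts(x, y, x_cuts, y_cuts):
    """Cell counts of the paired sample on the grid defined by cut points.

    ``x_cuts``/``y_cuts`` are strictly increasing interior boundaries; ``k``
    cuts define ``k + 1`` bins covering the whole real line, so every point
    falls in exactly one cell.  An empty cut array yields a single bin.
    """
    x, y = _validate_pair(x, y)
    x_cuts = np.atleast_1d(np.asarray(x_cuts, dtype=float))
    y_cuts = np.atleast_1d(np.asarray(y_cuts, dtype=float))
    for cuts in (x_cuts, y_cuts):
        if cuts.size and not np.all(np.diff(cuts) > 0):
            raise ValueError("cut points must be strictly increasing")
    xi = np.digitize(x, x_cuts)
    yi = np.digitize(y, y_cuts)
    counts = np.zeros((x_cuts.size + 1, y_cuts.size + 1), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return counts


def mutual_information(counts):
    """Plug-in mutual information of a contingency table, in bits.

    Empty rows/columns contribute zero (0*log 0 := 0).  Raises on an
    all-zero or negative table.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n <= 0:
        raise ValueError("all-zero contingency table")
    p = c / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(px) - np.log2(py))
    return float(terms[mask].sum())


def _candidate_cuts(v):
    """Candidate cut points for one axis.

    Exhaustive midpoints between consecutive distinct values when the
    alphabet is small; otherwise a rank-equipartition subset of those
    midpoints of size < ``_CANDIDATE_POOL``.
    """
    u = np.unique(v)
    if u.size < 2:
        return np.empty(0)
    mids = (u[:-1] + u[1:]) / 2.0
    if u.size <= max(EXACT_ALPHABET, _CANDIDATE_POOL):
        return mids
    qs = np.quantile(v, np.linspace(0.0, 1.0, _CANDIDATE_POOL + 1)[1:-1])
    idx = np.unique(np.clip(np.searchsorted(u, qs), 1, u.size - 1))
    return (u[idx - 1] + u[idx]) / 2.0


def _boundaries(cut_subset):
    return [0] + [i + 1 for i in cut_subset]


def max_grid_mi(x, y, x_bins, y_bins):
    """Maximum mutual information over every (x_bins, y_bins) grid.

    Cut points between consecutive distinct values are the only placements
    that change the induced distribution, so for small alphabets the search
    is exhaustive and the result exact.  Requested bin counts that exceed
    the number of distinct values collapse to the largest feasible
    partition; if either axis cannot support 2 bins the result is 0.
    """
    x, y = _validate_pair(x, y)
    xc = _candidate_cuts(x)
    yc = _candidate_cuts(y)
    xb = min(int(x_bins), xc.size + 1)
    yb = min(int(y_bins), yc.size + 1)
    if xb < 2 or yb < 2:
        return 0.0
    finest = contingency_counts(x, y, xc, yc)
    best = 0.0
    for xs in combinations(range(xc.size), xb - 1):
        fx = np.add.reduceat(finest, _boundaries(xs), axis=0)
        for ys in combinations(range(yc.size), yb - 1):
            table = np.add.reduceat(fx, _boundaries(ys), axis=1)
            best = max(best, mutual_information(table))
    return best


def characteristic_matrix(x, y, exponent=DEFAULT_EXPONENT):
    """Characteristic matrix of normalised maximised mutual information.

    Populates every grid size ``2 <= x_bins, 2 <= y_bins`` with
    ``x_bins * y_bins < B(n) = n ** exponent``, clipped to the feasible
    alphabet of each axis.  Raises :class:`GridBoundError` when B(n) admits
    no 2x2 grid.
    """
    x, y = _validate_pair(x, y)
    if not 0.0 < exponent < 1.0:
        raise ValueError("exponent must lie in (0, 1)")
    n = x.size
    bound = float(n) ** exponent
    if bound <= 4.0:
        raise GridBoundError(
            f"grid bound B({n}) = {bound:.3f} admits no 2x2 grid; "
            "increase n or the exponent"
        )
    kx = _candidate_cuts(x).size + 1
    ky = _candidate_cuts(y).size + 1
    entries = {}
    for xb in range(2, kx + 1):
        if xb * 2 >= bound:
            break
        for yb in range(2, ky + 1):
            if xb * yb >= bound:
                break
            denom = np.log2(min(xb, yb))
            entries[(xb, yb)] = max_grid_mi(x, y, xb, yb) / denom
    return CharacteristicMatrix(entries=entries, grid_bound=bound, n=n,
                                exponent=exponent)


def mic(x, y, exponent=DEFAULT_EXPONENT):
    """Maximal information coefficient of a paired sample.

    Returns a :class:`MicResult`.  A constant axis admits no 2-bin
    partition; such pairs score 0 by convention (independence is the only
    defensible reading for a degenerate variable).
    """
    x, y = _validate_pair(x, y)
    n = x.size
    bound = float(n) ** exponent
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return MicResult(0.0, 0, 0, bound, exponent)
    cm = characteristic_matrix(x, y, exponent=exponent)
    if not cm.entries:
        return MicResult(0.0, 0, 0, bound, exponent)
    (bx, by), value = cm.max_entry()
    return MicResult(float(value), bx, by, bound, exponent)


# ---------------------------------------------------------------------------
# Fast exact path for 3x3 genotype contingency tables.
#
# Genotype vectors take values in {0, 1, 2}, so every grid that can matter is
# a grouping of consecutive genotype values on each axis: one 3-bin partition
# and two 2-bin partitions per axis.  MIC then reduces to nine merged tables
# of the full 3x3 joint count table.  This is the workhorse of the
# permutation test, vectorised over batches of tables.
# ---------------------------------------------------------------------------

_PARTS = {
    3: [np.eye(3)],
    2: [
        np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),  # {0,1} | {2}
        np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]]),  # {0} | {1,2}
    ],
}


def _mi_batch(tables):
    """Mutual information (bits) for a batch of tables shaped (..., r, c)."""
    t = np.asarray(tables, dtype=float)
    n = t.sum(axis=(-2, -1), keepdims=True)
    n = np.where(n > 0, n, 1.0)
    p = t / n
    px = p.sum(axis=-1, keepdims=True)
    py = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(px) - np.log2(py))
    return np.where(p > 0, terms, 0.0).sum(axis=(-2, -1))


def mic_counts_3x3(tables, grid_bound):
    """Exact MIC for batches of 3x3 genotype contingency tables.

    ``tables`` has shape ``(..., 3, 3)``; the result drops the trailing two
    axes.  ``grid_bound`` is B(n) for the sample the counts summarise; grids
    with ``x_bins * y_bins >= grid_bound`` are excluded from the search.
    """
    if grid_bound <= 4.0:
        raise GridBoundError(
            f"grid bound {grid_bound:.3f} admits no 2x2 grid"
        )
    t = np.asarray(tables, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError("tables must have trailing shape (3, 3)")
    best = np.zeros(t.shape[:-2])
    for bx in (2, 3):
        for by in (2, 3):
            if bx * by >= grid_bound:
                continue
            denom = np.log2(min(bx, by))
            for rows in _PARTS[bx]:
                merged_rows = np.einsum("ab,...bc->...ac", rows, t)
                for cols in _PARTS[by]:
                    merged = np.einsum("...ac,dc->...ad", merged_rows, cols)
                    np.maximum(best, _mi_batch(merged) / denom, out=best)
    return best if best.ndim else float(best)
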