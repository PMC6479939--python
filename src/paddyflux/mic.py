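"""Maximal information coefficient (MIC) between two numeric vectors.

MIC scores the strength of linear and non-linear association on [0, 1].
For a grid that bins x into k columns and y into l rows, the normalised
mutual information is I(X;Y)/log2(min(k, l)); MIC is the maximum over
all grids with k·l ≤ B(n) = n^b (b = 0.6 by default, floored at 4 so the
2×2 grid is always admissible).  Grid lines may only fall between
distinct data values, so ties never straddle a bin edge.

Two search strategies sit behind one estimator:

* **exhaustive** — enumerate every admissible tie-respecting grid and
  take the true maximum.  Used automatically whenever the enumeration
  is small (budget-controlled), e.g. for small samples where the grid
  budget only admits coarse grids.
* **approximate** — the MINE-style heuristic: equipartition one axis,
  collapse the other axis into clumps of identical row membership
  (capped at c·k superclumps), and optimise the column boundaries by
  dynamic programming; both orientations are tried for every grid size.

Both respect the same grid budget, so the approximate search can only
undershoot the exhaustive optimum, never exceed it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

__all__ = ["NetworkConfig", "mic", "grid_budget"]


@dataclass(frozen=True)
class NetworkConfig:
    """MIC and co-occurrence network parameters.

    b_exponent sets the grid budget B(n) = n^b; clump_factor c caps the
    clump count at c·k during column optimisation (the original MINE
    convention is c = 15); edge_threshold is the minimum MIC kept as a
    network edge; sign_method chooses the rank correlation whose sign
    decorates each (unsigned-MIC) edge.
    """

    b_exponent: float = 0.6
    clump_factor: int = 15
    edge_threshold: float = 0.6
    sign_method: str = "spearman"
    exhaustive: Optional[bool] = None
    max_exhaustive_grids: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 < self.b_exponent < 1.0:
            raise ValueError(f"b_exponent must lie in (0, 1), got {self.b_exponent}")
        if self.clump_factor < 1:
            raise ValueError(f"clump_factor must be >= 1, got {self.clump_factor}")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError(
                f"edge_threshold must lie in [0, 1], got {self.edge_threshold}"
            )
        if self.sign_method not in ("spearman", "pearson"):
            raise ValueError(f"unknown sign_method {self.sign_method!r}")


def grid_budget(n: int, b_exponent: float = 0.6) -> float:
    """Grid budget B(n) = n^b, floored at 4 so 2×2 is always admissible."""
    return max(float(n) ** b_exponent, 4.0)


def _grid_sizes(n: int, b_exponent: float) -> list[tuple[int, int]]:
    """All ordered (columns, rows) pairs with k, l >= 2 and k·l <= B(n)."""
    budget = grid_budget(n, b_exponent)
    out = []
    for k in range(2, int(budget // 2) + 1):
        for l in range(2, int(budget // k) + 1):
            out.append((k, l))
    return out


def _group_ids(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tie structure of one axis.

    Returns (gid, order, sizes): gid[i] is the rank of point i's distinct
    value, order sorts points by value (stable), sizes are the tie-group
    sizes in sorted order.
    """
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    steps = np.concatenate(([0], (sv[1:] != sv[:-1]).astype(np.int64)))
    gid_sorted = np.cumsum(steps)
    gid = np.empty(v.size, dtype=np.int64)
    gid[order] = gid_sorted
    sizes = np.bincount(gid_sorted)
    return gid, order, sizes


def _mi_bits(xa: np.ndarray, ya: np.ndarray, k: int, l: int) -> float:
    n = xa.size
    joint = np.bincount(xa * l + ya, minlength=k * l).reshape(k, l) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def _exhaustive_mic(
    gx: np.ndarray, gy: np.ndarray, gx_n: int, gy_n: int, grids: Sequence[tuple[int, int]]
) -> float:
    best = 0.0
    for k, l in grids:
        if k > gx_n or l > gy_n:
            continue
        norm = math.log2(min(k, l))
        for xc in combinations(range(1, gx_n), k - 1):
            xa = np.searchsorted(np.asarray(xc), gx, side="right")
            for yc in combinations(range(1, gy_n), l - 1):
                ya = np.searchsorted(np.asarray(yc), gy, side="right")
                best = max(best, _mi_bits(xa, ya, k, l) / norm)
    return min(best, 1.0)


def _enumeration_cost(
    gx_n: int, gy_n: int, grids: Sequence[tuple[int, int]]
) -> int:
    cost = 0
    for k, l in grids:
        if k > gx_n or l > gy_n:
            continue
        cost += math.comb(gx_n - 1, k - 1) * math.comb(gy_n - 1, l - 1)
    return cost


def _equipartition_bins(group_sizes: np.ndarray, l: int) -> np.ndarray:
    """Assign consecutive tie-groups to <= l size-balanced bins.

    Boundaries go to the group edge whose cumulative count is closest to
    the ideal quantile j·n/l; ties are never split.
    """
    g = group_sizes.size
    if g <= l:
        return np.arange(g, dtype=np.int64)
    cum = np.cumsum(group_sizes)
    n = cum[-1]
    bins = np.zeros(g, dtype=np.int64)
    prev = 0
    for j in range(1, l):
        hi = g - (l - j)  # leave room for the remaining boundaries
        if prev > hi - 1:
            break
        ideal = j * n / l
        cand = range(prev, hi)
        best_i = min(cand, key=lambda i: (abs(cum[i] - ideal), i))
        bins[best_i + 1 :] += 1
        prev = best_i + 1
    return bins


def _clump_counts(
    rows_sorted: np.ndarray, unit_sizes: np.ndarray, n_rows: int
) -> np.ndarray:
    """Row-count matrix of x-axis clumps.

    Units are x tie-groups in sorted order; consecutive units lying
    entirely in the same row merge into one clump.
    """
    n_units = unit_sizes.size
    unit_of_point = np.repeat(np.arange(n_units), unit_sizes)
    counts = np.zeros((n_units, n_rows))
    np.add.at(counts, (unit_of_point, rows_sorted), 1.0)
    merged: list[np.ndarray] = []
    last_row = -2  # row index if previous clump is pure, else -2
    for c in counts:
        nz = np.flatnonzero(c)
        row = nz[0] if nz.size == 1 else -1
        if row >= 0 and row == last_row:
            merged[-1] = merged[-1] + c
        else:
            merged.append(c.copy())
            last_row = row if row >= 0 else -2
            continue
        last_row = row
    return np.asarray(merged)


def _superclumps(counts: np.ndarray, cap: int) -> np.ndarray:
    if counts.shape[0] <= cap:
        return counts
    sizes = counts.sum(axis=1)
    bins = _equipartition_bins(sizes, cap)
    out = np.zeros((int(bins[-1]) + 1, counts.shape[1]))
    np.add.at(out, bins, counts)
    return out


def _max_mi_columns(counts: np.ndarray, max_cols: int) -> float:
    """Maximum I(columns; rows) over partitions of the clump sequence
    into at most max_cols contiguous columns (exact dynamic program)."""
    k_clumps, _ = counts.shape
    cum = np.vstack([np.zeros((1, counts.shape[1])), np.cumsum(counts, axis=0)])
    n = cum[-1].sum()
    # W[i, t]: sum_q (c_q/n) log2(c_q/m) for the column spanning clumps [i, t)
    span = cum[None, :, :] - cum[:, None, :]
    m = span.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(span > 0, span / n * np.log2(span / m), 0.0)
    w = term.sum(axis=-1)
    valid = np.triu(np.ones((k_clumps + 1, k_clumps + 1), dtype=bool), 1)
    w = np.where(valid, w, -np.inf)

    pq = cum[-1] / n
    h_rows = -float(np.sum(np.where(pq > 0, pq * np.log2(pq), 0.0)))

    best_prev = w[0].copy()  # one column covering clumps [0, t)
    best_full = -np.inf
    for _ in range(2, max_cols + 1):
        best_new = (best_prev[:, None] + w).max(axis=0)
        best_full = max(best_full, best_new[k_clumps])
        best_prev = best_new
    if not np.isfinite(best_full):
        return 0.0
    return max(h_rows + best_full, 0.0)


def _heuristic_candidate(
    opt_gid: np.ndarray,
    opt_order: np.ndarray,
    opt_sizes: np.ndarray,
    fix_gid: np.ndarray,
    fix_sizes: np.ndarray,
    k_cols: int,
    l_rows: int,
    clump_factor: int,
) -> float:
    """One characteristic-matrix candidate: equipartition the *fix* axis
    into l_rows, optimise the *opt* axis into <= k_cols columns."""
    row_of_group = _equipartition_bins(fix_sizes, l_rows)
    rows = row_of_group[fix_gid]
    n_rows = int(row_of_group.max()) + 1
    if n_rows < 2:
        return 0.0
    counts = _clump_counts(rows[opt_order], opt_sizes, n_rows)
    counts = _superclumps(counts, clump_factor * k_cols)
    mi = _max_mi_columns(counts, k_cols)
    return mi / math.log2(min(k_cols, l_rows))


def mic(
    x: Sequence[float],
    y: Sequence[float],
    config: NetworkConfig | None = None,
) -> float:
    """Maximal information coefficient of two equal-length vectors.

    Symmetric in its arguments and always in [0, 1].  A constant vector
    (or a sample too small to bin) yields 0.0 with a warning rather than
    an error.  The search is exhaustive over all admissible grids when
    the enumeration is cheap, MINE-style approximate otherwise; see the
    module docstring.
    """
    cfg = config or NetworkConfig()
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size != ya.size:
        raise ValueError(
            f"x and y must be equal-length 1-D vectors, got {xa.shape} and {ya.shape}"
        )
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("MIC inputs must be finite")
    n = xa.size
    if n < 10:
        warnings.warn(f"sample size {n} too small for MIC; returning 0", stacklevel=2)
        return 0.0

    gx, ox, sx = _group_ids(xa)
    gy, oy, sy = _group_ids(ya)
    gx_n, gy_n = sx.size, sy.size
    if gx_n < 2 or gy_n < 2:
        warnings.warn("constant vector has no association; MIC = 0", stacklevel=2)
        return 0.0

    grids = _grid_sizes(n, cfg.b_exponent)
    use_exhaustive = cfg.exhaustive
    if use_exhaustive is None:
        use_exhaustive = (
            _enumeration_cost(gx_n, gy_n, grids) <= cfg.max_exhaustive_grids
        )
    if use_exhaustive:
        return _exhaustive_mic(gx, gy, gx_n, gy_n, grids)

    best = 0.0
    for k, l in grids:
        best = max(
            best,
            _heuristic_candidate(gx, ox, sx, gy, sy, k, l, cfg.clump_factor),
            _heuristic_candidate(gy, oy, sy, gx, sx, k, l, cfg.clump_factor),
        )
    return min(best, 1.0)
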