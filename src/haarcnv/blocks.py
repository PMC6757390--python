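"""Compressive block generator: breakpoint array + integral array.

A *block generator* must, for any threshold ``lam``, produce the ordered
blocks of the Haar-regression partition of the signal together with their
Gaussian sufficient statistics (n, sum, sum of squares).  Two sub-structures
do this without ever materializing the regression:

* :class:`IntegralArray` — cell-partitioned partial cumulative sums of
  per-position sufficient statistics.  Within each cell of size ``c`` the
  sums run from high to low indices, so any interval [s, e) is a sum of one
  partial entry, whole-cell entries, and one subtracted partial entry:
  O(1 + (e-s)/c) work with bounded floating-point cancellation.

* :class:`BreakpointArray` — the boundary weight vector plus capped jump
  distances such that every weight inside a stretch is strictly below the
  weight at its head.  Finding the next position with weight >= lam is
  pointer chasing over left-to-right maxima: expected O(log N) jumps for a
  block of N positions in random order.

The deliberately *subcompressive* wavelet-tree traversal
(:func:`wavelet_tree_blocks`) is retained purely as a reference for tests;
it emits extra boundaries at the central discontinuities of internal tree
nodes whose subtree maximum, but not their own coefficient, clears the
threshold.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .wavelets import Signal, WeightVector, maxlet_transform

__all__ = [
    "SuffStats",
    "IntegralArray",
    "BreakpointArray",
    "Block",
    "build_integral_array",
    "query_stats",
    "build_breakpoint_array",
    "next_breakpoint",
    "iter_blocks",
    "block_boundaries",
    "wavelet_tree_blocks",
    "DEFAULT_CELL_SIZE",
    "DEFAULT_MAX_JUMP",
]

DEFAULT_CELL_SIZE = 65_536
DEFAULT_MAX_JUMP = 65_536


@dataclass(frozen=True)
class SuffStats:
    """Sufficient statistics of a set of positions under a Gaussian model."""

    n: int
    sum: float
    sumsq: float

    def __add__(self, other: "SuffStats") -> "SuffStats":
        return SuffStats(self.n + other.n, self.sum + other.sum, self.sumsq + other.sumsq)

    def __sub__(self, other: "SuffStats") -> "SuffStats":
        return SuffStats(self.n - other.n, self.sum - other.sum, self.sumsq - other.sumsq)


@dataclass(frozen=True)
class Block:
    """Half-open block [start, end) with its sufficient statistics."""

    start: int
    end: int
    stats: SuffStats


class IntegralArray:
    """Cell-partitioned integral array over (y, y^2) sufficient statistics."""

    def __init__(self, sums: np.ndarray, sumsqs: np.ndarray, cell_size: int, T: int):
        self.sums = sums        # length T+1, entry T is the zero sentinel
        self.sumsqs = sumsqs
        self.cell_size = cell_size
        self.T = T


def build_integral_array(signal: Signal, cell_size: int = DEFAULT_CELL_SIZE) -> IntegralArray:
    """One linear pass; entry t holds the sum from t to the end of its cell."""
    if not isinstance(signal, Signal):
        signal = Signal(np.asarray(signal))
    if cell_size < 1:
        raise ValueError("cell_size must be >= 1")
    y = signal.values
    T = y.size
    sums = np.zeros(T + 1)
    sumsqs = np.zeros(T + 1)
    ysq = y * y
    for a in range(0, T, cell_size):
        b = min(a + cell_size, T)
        sums[a:b] = np.cumsum(y[a:b][::-1])[::-1]
        sumsqs[a:b] = np.cumsum(ysq[a:b][::-1])[::-1]
    return IntegralArray(sums, sumsqs, cell_size, T)


def query_stats(v: IntegralArray, s: int, e: int) -> SuffStats:
    """Statistics of [s, e): v[s] + interior whole-cell entries − v[e] if partial."""
    if not (0 <= s < e <= v.T):
        raise ValueError(f"invalid interval [{s}, {e}) for T={v.T}")
    c = v.cell_size
    total_sum = v.sums[s]
    total_sumsq = v.sumsqs[s]
    m = (s // c + 1) * c
    if m < e:
        interior = np.arange(m, e, c)
        total_sum += v.sums[interior].sum()
        total_sumsq += v.sumsqs[interior].sum()
    if e % c != 0:
        total_sum -= v.sums[e]
        total_sumsq -= v.sumsqs[e]
    return SuffStats(e - s, float(total_sum), float(total_sumsq))


class BreakpointArray:
    """Boundary weights plus capped maximal jump distances (stretches)."""

    def __init__(self, weights: WeightVector, jumps: np.ndarray, max_jump: int,
                 max_queue_len: int, final_queue_len: int):
        if weights.role != "boundary":
            raise ValueError("BreakpointArray requires boundary-role weights")
        self.weights = weights
        self.jumps = jumps
        self.max_jump = max_jump
        #: peak deque occupancy observed during construction
        self.max_queue_len = max_queue_len
        #: deque occupancy after the final push (the left-to-right record count)
        self.final_queue_len = final_queue_len

    @property
    def T(self) -> int:
        return len(self.weights)


def build_breakpoint_array(weights: WeightVector, max_jump: int = DEFAULT_MAX_JUMP) -> BreakpointArray:
    """Single left-to-right pass with a deque of pending indices.

    An index is finalized (its jump distance fixed) when a weight at least
    as large arrives, or when it falls ``max_jump`` positions behind the
    cursor.  Pending indices at the end of the pass stretch to the end of
    the data, capped at ``max_jump``.
    """
    if weights.role != "boundary":
        raise ValueError("build_breakpoint_array expects boundary-role weights")
    if max_jump < 1:
        raise ValueError("max_jump must be >= 1")
    w = weights.values.tolist()
    T = len(w)
    jumps = np.ones(T, dtype=np.int64)
    dq: deque[int] = deque()
    max_len = 0
    for t in range(T):
        if dq and t - dq[0] >= max_jump:
            jumps[dq.popleft()] = max_jump
        wt = w[t]
        while dq and w[dq[-1]] <= wt:
            i = dq.pop()
            jumps[i] = t - i
        dq.append(t)
        if len(dq) > max_len:
            max_len = len(dq)
    final_len = len(dq)
    for i in dq:
        jumps[i] = min(T - i, max_jump)
    return BreakpointArray(weights, jumps, max_jump, max_len, final_len)


def next_breakpoint(bpa: BreakpointArray, start: int, lam: float) -> int:
    """Smallest t >= start with weight >= lam, or T if none; pointer chasing."""
    T = bpa.T
    if not (0 <= start <= T):
        raise ValueError(f"start {start} out of range for T={T}")
    w = bpa.weights.values
    jumps = bpa.jumps
    t = start
    while t < T and w[t] < lam:
        t += jumps[t]
    return min(t, T)


def block_boundaries(bpa: BreakpointArray, lam: float) -> list[int]:
    """Ordered block start positions at threshold lam (always includes 0)."""
    bounds = [0]
    T = bpa.T
    t = next_breakpoint(bpa, 1, lam)
    while t < T:
        bounds.append(t)
        t = next_breakpoint(bpa, t + 1, lam)
    return bounds


def iter_blocks(bpa: BreakpointArray, v: IntegralArray, lam: float) -> Iterator[Block]:
    """Consecutive, gapless blocks of [0, T) at threshold lam."""
    if bpa.T != v.T:
        raise ValueError("breakpoint array and integral array cover different lengths")
    s = 0
    T = bpa.T
    while s < T:
        e = next_breakpoint(bpa, s + 1, lam)
        yield Block(s, e, query_stats(v, s, e))
        s = e


def wavelet_tree_blocks(signal: Signal, lam: float) -> list[Block]:
    """Subcompressive wavelet-tree reference block generator (test oracle).

    Nodes store subtree maxima of |d|; DFS recurses into any node whose
    subtree maximum reaches ``lam``, emitting a boundary at its central
    discontinuity, and nodes whose own coefficient reaches ``lam`` emit
    their side discontinuities as well.  Never used by the sampler.
    """
    if not isinstance(signal, Signal):
        signal = Signal(np.asarray(signal))
    T = signal.T
    y = signal.values
    m = maxlet_transform(signal).values
    boundaries: set[int] = {0}
    if T > 1:
        J = 1
        while (1 << J) < T:
            J += 1
        # node (j, k): own |d| read from the maxlet layout at b_center.
        # Nodes with b_center >= T are virtual (the padded tree's tail):
        # they store no coefficient but their subtrees may hold real nodes.

        def subtree_max(j: int, k: int) -> float:
            center = (1 << j) * k + (1 << (j - 1))
            s = m[center] if center < T else -math.inf
            if j > 1 and (1 << (j - 1)) * 2 * k < T:
                s = max(s, subtree_max(j - 1, 2 * k), subtree_max(j - 1, 2 * k + 1))
            return s

        def visit(j: int, k: int) -> None:
            center = (1 << j) * k + (1 << (j - 1))
            if (1 << j) * k >= T:
                return
            if subtree_max(j, k) >= lam:
                if center < T:
                    boundaries.add(center)
                    if m[center] >= lam:
                        boundaries.add((1 << j) * k)
                        right = (1 << j) * (k + 1)
                        if right < T:
                            boundaries.add(right)
                if j > 1:
                    visit(j - 1, 2 * k)
                    visit(j - 1, 2 * k + 1)

        visit(J, 0)
    bounds = sorted(boundaries) + [T]
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        seg = y[s:e]
        out.append(Block(s, e, SuffStats(e - s, float(seg.sum()), float((seg * seg).sum()))))
    return out
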