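"""Run-length encoded posterior marginal state counts, and segment calling.

Across Gibbs iterations we must count, for every position t and state s, how
often s was sampled at t.  A dense T x S count matrix is wasteful: sampled
paths are piecewise constant over blocks, and most positions only ever see a
handful of states.  Instead the history is kept as a queue of run-length
segments, each carrying a compressed per-state count vector of signed
integers:

* a negative entry -c records c observations of the current state, after
  which the current state advances by one;
* a positive entry jumps the current state to that value (skipping a run of
  zero-count states with a single number); index values must be strictly
  increasing and never redundant;
* a zero marks a segment start in the flat queue serialization.

For example ``(-2, 3, -8, -1, -4, 9, -5)`` decodes against the running
states ``(0, 1, 3, 4, 5, 6, 9)`` to counts {0: 2, 3: 8, 4: 1, 5: 4, 9: 5}.

Adding one iteration's state path is a single merge-walk: segments are
cycled front-to-back through the queue once, split wherever a sampled-run
boundary falls inside them, and each piece folds one more count for its
run's state into its encoding.  With M segments and S states the whole
structure holds at most (2S + 1) M entries.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateRuns",
    "CountEncoding",
    "MarginalRecords",
    "SegmentCall",
    "init_records",
    "add_run_lengths",
    "decode_segment",
    "encode_counts",
    "query_counts",
    "call_segments",
]

#: one sampled state path as (run length, state) pairs; lengths sum to T
StateRuns = list[tuple[int, int]]

#: per-segment compressed counts (without the leading 0 segment marker)
CountEncoding = tuple[int, ...]


class MarginalRecordError(ValueError):
    """Raised when an encoding violates the marginal-record invariants."""


def decode_segment(encoding: CountEncoding) -> dict[int, int]:
    """Invert the signed-integer encoding into a state -> count map."""
    counts: dict[int, int] = {}
    state = 0
    for entry in encoding:
        if entry < 0:
            counts[state] = counts.get(state, 0) - entry
            state += 1
        elif entry > 0:
            if entry <= state:
                raise MarginalRecordError(
                    f"index value {entry} not above current state {state}")
            state = entry
        else:
            raise MarginalRecordError("zero entry inside a segment encoding")
    return counts


def encode_counts(counts: dict[int, int]) -> CountEncoding:
    """Encode a state -> count map; inverse of :func:`decode_segment`."""
    out: list[int] = []
    state = 0
    for s in sorted(counts):
        c = counts[s]
        if c <= 0:
            raise MarginalRecordError("counts must be positive")
        if s < state:
            raise MarginalRecordError("states must be strictly increasing")
        if s > state:
            out.append(s)
            state = s
        out.append(-c)
        state += 1
    return tuple(out)


def _fold_count(encoding: CountEncoding, state: int) -> CountEncoding:
    """Encoding with one extra count for ``state`` folded in."""
    counts = decode_segment(encoding)
    counts[state] = counts.get(state, 0) + 1
    return encode_counts(counts)


@dataclass
class _Segment:
    length: int
    encoding: CountEncoding


class MarginalRecords:
    """Queue of run-length segments tiling [0, T) with compressed counts."""

    def __init__(self, T: int):
        if T <= 0:
            raise ValueError("T must be positive")
        self.T = T
        self.iterations = 0
        self._queue: deque[_Segment] = deque([_Segment(T, ())])

    @property
    def n_segments(self) -> int:
        return len(self._queue)

    @property
    def s_max(self) -> int:
        """Highest state index with a recorded count (-1 if none)."""
        best = -1
        for seg in self._queue:
            for s in decode_segment(seg.encoding):
                best = max(best, s)
        return best

    def total_entries(self) -> int:
        """Entries across the queue, counting one segment-start marker each."""
        return sum(1 + len(seg.encoding) for seg in self._queue)

    def segments(self) -> list[tuple[int, int, dict[int, int]]]:
        """Decoded view: ordered (start, end, counts) triples."""
        out = []
        start = 0
        for seg in self._queue:
            out.append((start, start + seg.length, decode_segment(seg.encoding)))
            start += seg.length
        return out

    def dense_counts(self, n_states: int | None = None) -> np.ndarray:
        """Materialize the full T x S count matrix (small data only)."""
        S = (self.s_max + 1) if n_states is None else n_states
        S = max(S, 1)
        out = np.zeros((self.T, S), dtype=np.int64)
        for start, end, counts in self.segments():
            for s, c in counts.items():
                out[start:end, s] = c
        return out


def init_records(T: int) -> MarginalRecords:
    """Empty records: one zero-count segment covering [0, T)."""
    return MarginalRecords(T)


def add_run_lengths(records: MarginalRecords, runs: StateRuns) -> MarginalRecords:
    """Fold one sampled state path into the records (single merge-walk).

    Cycles each existing segment front-to-back exactly once; a segment
    containing a run boundary is split, and every resulting piece gains one
    count for its run's state.  O(#segments + #runs).
    """
    total = sum(length for length, _ in runs)
    if total != records.T:
        raise ValueError(f"run lengths sum to {total}, expected T={records.T}")
    if any(length <= 0 for length, _ in runs):
        raise ValueError("run lengths must be positive")
    queue = records._queue
    run_iter = iter(runs)
    run_len, run_state = next(run_iter)
    remaining = len(queue)
    while remaining > 0:
        seg = queue.popleft()
        remaining -= 1
        seg_left = seg.length
        while seg_left > 0:
            take = min(seg_left, run_len)
            queue.append(_Segment(take, _fold_count(seg.encoding, run_state)))
            seg_left -= take
            run_len -= take
            if run_len == 0:
                nxt = next(run_iter, None)
                if nxt is not None:
                    run_len, run_state = nxt
    records.iterations += 1
    return records


def query_counts(records: MarginalRecords, t: int) -> dict[int, int]:
    """State -> count map of the segment containing position t."""
    if not (0 <= t < records.T):
        raise ValueError(f"position {t} out of range for T={records.T}")
    start = 0
    for seg in records._queue:
        if start <= t < start + seg.length:
            return decode_segment(seg.encoding)
        start += seg.length
    raise AssertionError("segments do not tile [0, T)")  # pragma: no cover


@dataclass(frozen=True)
class SegmentCall:
    """A putative copy-number segment (window coordinates, half-open)."""

    start: int
    end: int
    state: int
    posterior: float   # average fraction of iterations with the modal state
    mean: float        # emission mean of the modal state at calling time


def call_segments(records: MarginalRecords, state_means: np.ndarray,
                  min_abs_mean: float = 1.0) -> list[SegmentCall]:
    """Call segments whose modal state has |mean| >= min_abs_mean.

    Modal state per segment by recorded count (ties go to the lower state
    index); adjacent segments sharing a modal state are merged; merged
    segments whose modal-state mean has absolute value at least
    ``min_abs_mean`` are returned in order.
    """
    if records.iterations < 1:
        raise ValueError("no iterations recorded")
    if hasattr(state_means, "mu"):  # accept EmissionParams directly
        state_means = state_means.mu
    state_means = np.asarray(state_means, dtype=np.float64)
    R = records.iterations
    merged: list[list] = []  # [start, end, state, sum(len * modal_count)]
    for start, end, counts in records.segments():
        modal = min((s for s in counts), key=lambda s: (-counts[s], s))
        mcount = counts[modal]
        if merged and merged[-1][2] == modal and merged[-1][1] == start:
            merged[-1][1] = end
            merged[-1][3] += (end - start) * mcount
        else:
            merged.append([start, end, modal, (end - start) * mcount])
    calls = []
    for start, end, modal, weight in merged:
        if modal < state_means.size and abs(state_means[modal]) >= min_abs_mean:
            posterior = weight / (R * (end - start))
            calls.append(SegmentCall(start, end, modal, float(posterior),
                                     float(state_means[modal])))
    return calls
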