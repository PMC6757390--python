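"""Track reading/writing, preprocessing, and BED output.

Input tracks are either plain text (one value per line) or 4-column
bedGraph (chrom, start, end, value; 0-based half-open, expanded to one
value per covered position).  Preprocessing mirrors the differential
read-depth pipeline: subtract a control track from the case track, then
average over non-overlapping windows to approximate Gaussian noise.  Calls
are written as BED5+ with window coordinates rescaled back to bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marginals import SegmentCall
from .wavelets import Signal

__all__ = [
    "Track",
    "read_track",
    "read_tracks",
    "subtract_tracks",
    "window_average",
    "n_windows",
    "write_bed",
    "read_bed",
    "write_marginals_tsv",
    "write_trace_tsv",
]


@dataclass
class Track:
    """Per-position values of one chromosome (or an unnamed plain track)."""

    values: np.ndarray
    chrom: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("track values must be 1-d")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    def __len__(self) -> int:
        return self.values.size


class TrackParseError(ValueError):
    """Malformed track file; carries the 1-based offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".bedgraph", ".bg", ".bedgraph.txt")):
        return "bedgraph"
    return "plain"


def read_tracks(path, fmt: str | None = None) -> list[Track]:
    """Read a track file into one Track per chromosome (plain: a single one)."""
    fmt = fmt or _infer_format(path)
    if fmt == "plain":
        values = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    values.append(float(line))
                except ValueError:
                    raise TrackParseError(path, i, f"not a number: {line!r}") from None
        if not values:
            raise TrackParseError(path, 1, "empty track")
        return [Track(np.asarray(values))]
    if fmt != "bedgraph":
        raise ValueError(f"unknown track format {fmt!r}")
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise TrackParseError(path, i, "expected 4 columns (chrom start end value)")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError:
                raise TrackParseError(path, i, f"malformed bedGraph row: {line!r}") from None
    if not rows:
        raise TrackParseError(path, 1, "empty track")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(ends <= starts):
            raise ValueError(f"{path}: empty or inverted interval on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
        length = int(ends[-1] - starts[0])
        values = np.zeros(length)
        offset = int(starts[0])
        for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
            values[s - offset:e - offset] = v
        tracks.append(Track(values, chrom=str(chrom)))
    return tracks


def read_track(path, fmt: str | None = None) -> Track:
    """Read a single-chromosome track; errors if the file holds several."""
    tracks = read_tracks(path, fmt)
    if len(tracks) > 1:
        chroms = ", ".join(t.chrom or "?" for t in tracks)
        raise ValueError(f"{path} contains multiple chromosomes ({chroms}); "
                         "use read_tracks()")
    return tracks[0]


def subtract_tracks(a: Track, b: Track) -> Track:
    """Elementwise case-minus-control differential track."""
    if len(a) != len(b):
        raise ValueError(f"track lengths differ: {len(a)} vs {len(b)}")
    if a.chrom is not None and b.chrom is not None and a.chrom != b.chrom:
        raise ValueError(f"chromosome mismatch: {a.chrom} vs {b.chrom}")
    return Track(a.values - b.values, chrom=a.chrom or b.chrom)


def n_windows(n: int, w: int) -> int:
    """Number of non-overlapping windows covering n positions."""
    if w < 1:
        raise ValueError("window width must be >= 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    return -(-n // w)  # ceil(n / w)


def window_average(values, w: int = 20) -> Signal:
    """Means over non-overlapping windows; final partial window averaged
    over its actual length."""
    if w < 1:
        raise ValueError("window width must be >= 1")
    if isinstance(values, Track):
        values = values.values
    values = np.asarray(values, dtype=np.float64)
    if w == 1:
        return Signal(values.copy())
    starts = np.arange(0, values.size, w)
    sums = np.add.reduceat(values, starts)
    counts = np.minimum(starts + w, values.size) - starts
    return Signal(sums / counts)


def write_bed(calls: list[SegmentCall], window: int, path, chrom: str = "chr1") -> None:
    """BED5+ output: base coordinates, modal state, 1000*posterior score, mean."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstate_mean\n")
        for call in calls:
            fh.write(f"{chrom}\t{call.start * window}\t{call.end * window}\t"
                     f"state{call.state}\t{round(1000 * call.posterior)}\t"
                     f"{call.mean:.6g}\n")


def read_bed(path) -> list[tuple[str, int, int, str, int, float]]:
    """Parse a BED5+ file written by :func:`write_bed` (round-trip helper)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name, score, mean = line.split("\t")
            out.append((chrom, int(start), int(end), name, int(score), float(mean)))
    return out


def write_marginals_tsv(records, path, n_states: int | None = None) -> None:
    """Segment-wise marginal counts: start, end, then one column per state."""
    S = max(records.s_max + 1, 1) if n_states is None else n_states
    with open(path, "w") as fh:
        fh.write("start\tend\t" + "\t".join(f"state{s}" for s in range(S)) + "\n")
        for start, end, counts in records.segments():
            row = [str(counts.get(s, 0)) for s in range(S)]
            fh.write(f"{start}\t{end}\t" + "\t".join(row) + "\n")


def write_trace_tsv(trace, path) -> None:
    """Per-iteration threshold, block count and smallest sampled variance."""
    with open(path, "w") as fh:
        fh.write("iteration\tthreshold\tn_blocks\tmin_var\n")
        for i, (lam, nb, mv) in enumerate(zip(trace.thresholds, trace.n_blocks,
                                              trace.min_var)):
            fh.write(f"{i}\t{lam:.10g}\t{nb}\t{mv:.10g}\n")
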