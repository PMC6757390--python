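"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators:

* :func:`gen_piecewise` — the segmentation model itself: a piecewise
  constant mean sequence plus i.i.d. centered Gaussian noise.

* :func:`gen_differential_coverage` — the differential read-depth pipeline:
  two Poisson count tracks (case and control) sharing a smooth additive
  coverage bias, where only the case track's rate scales with copy number.
  Subtracting control from case cancels the shared bias in expectation, and
  averaging over non-overlapping windows (default 20 positions) makes the
  residual noise approximately Gaussian.  Copy number 2 is diploid; a track
  simulated at ``mean_coverage`` x per haplotype pair means a full 2-copy
  gain shifts the windowed differential mean by ``mean_coverage``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tracks import window_average
from .wavelets import Signal

__all__ = ["GroundTruth", "TruthSegment", "gen_piecewise", "gen_differential_coverage"]


@dataclass(frozen=True)
class TruthSegment:
    start: int
    end: int
    mean: float
    state: int


@dataclass(frozen=True)
class GroundTruth:
    """True segmentation underlying a simulated signal."""

    segments: tuple[TruthSegment, ...]
    sigma: float
    seed: int | None

    @property
    def T(self) -> int:
        return self.segments[-1].end

    def mean_vector(self) -> np.ndarray:
        out = np.empty(self.T)
        for seg in self.segments:
            out[seg.start:seg.end] = seg.mean
        return out

    def state_vector(self) -> np.ndarray:
        out = np.empty(self.T, dtype=np.int64)
        for seg in self.segments:
            out[seg.start:seg.end] = seg.state
        return out


def gen_piecewise(T: int, n_segments: int, mean_levels, sigma: float,
                  seed: int | None = None) -> tuple[Signal, GroundTruth]:
    """Piecewise-constant signal with Gaussian noise and known truth.

    Segment boundaries are drawn uniformly without replacement; each
    segment's mean is drawn from ``mean_levels`` (adjacent segments are
    forced to differ when possible, so every boundary is a real change
    point).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > T:
        raise ValueError("cannot fit more segments than positions")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    mean_levels = np.asarray(mean_levels, dtype=np.float64)
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.choice(np.arange(1, T), size=n_segments - 1, replace=False)) \
        if n_segments > 1 else np.array([], dtype=np.int64)
    bounds = np.concatenate(([0], cuts, [T]))
    segments = []
    prev_level = None
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        choices = np.arange(mean_levels.size)
        if prev_level is not None and mean_levels.size > 1:
            choices = choices[choices != prev_level]
        level = int(rng.choice(choices))
        prev_level = level
        segments.append(TruthSegment(int(a), int(b), float(mean_levels[level]), level))
    truth = GroundTruth(tuple(segments), float(sigma), seed)
    y = truth.mean_vector()
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=T)
    return Signal(y), truth


def _smooth_bias(T: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency sinusoid mixture, the shared additive coverage bias."""
    if amplitude == 0:
        return np.zeros(T)
    t = np.arange(T) / T
    bias = np.zeros(T)
    for freq in (1, 2, 3, 5):
        bias += rng.normal(0, 1) * np.sin(2 * math.pi * freq * t + rng.uniform(0, 2 * math.pi))
    bias *= amplitude / max(np.abs(bias).max(), 1e-12)
    return bias


def gen_differential_coverage(T: int, cnv_spec, mean_coverage: float = 4.0,
                              bias_amplitude: float = 0.0, window: int = 20,
                              seed: int | None = None):
    """Two-track Poisson simulator of the differential read-depth pipeline.

    ``cnv_spec`` is a list of (start, end, copy_number) triples in base
    coordinates for the case track (copy number 2 elsewhere).  Returns
    (case counts, control counts, windowed differential Signal, truth in
    window coordinates).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    rng = np.random.default_rng(seed)
    bias = _smooth_bias(T, bias_amplitude, rng)
    copy = np.full(T, 2.0)
    for start, end, cn in cnv_spec:
        if not (0 <= start < end <= T):
            raise ValueError(f"bad CNV interval [{start}, {end})")
        copy[start:end] = cn
    rate_control = np.clip(mean_coverage + bias, 0.0, None)
    rate_case = np.clip(mean_coverage * copy / 2.0 + bias, 0.0, None)
    case = rng.poisson(rate_case).astype(np.int64)
    control = rng.poisson(rate_control).astype(np.int64)
    diff = window_average((case - control).astype(np.float64), window)
    # truth in window coordinates: expected windowed differential mean
    expected = window_average(mean_coverage * (copy / 2.0 - 1.0), window)
    n_win = diff.T
    boundaries = sorted({0, n_win} | {
        b for start, end, _ in cnv_spec
        for b in (start // window, -(-end // window)) if 0 < b < n_win})
    segments = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        mean = float(expected.values[a:b].mean())
        state = 0 if abs(mean) < 1e-9 else (1 if mean > 0 else -1)
        segments.append(TruthSegment(a, b, mean, state))
    sigma_w = math.sqrt(2.0 * mean_coverage / window)  # CLT scale of window means
    truth = GroundTruth(tuple(segments), sigma_w, seed)
    return case, control, diff, truth
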