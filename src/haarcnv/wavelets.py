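"""Haar breakpoint weights via the in-place maxlet and boundary transforms.

The discrete Haar wavelet at scale ``j >= 1``, shift ``k >= 0`` is

    psi_{j,k}[t] = +1/sqrt(2^j)   for  2^j*k       <= t < 2^j*(k+1/2)
                   -1/sqrt(2^j)   for  2^j*(k+1/2) <= t < 2^j*(k+1)

with detail coefficient ``d_{j,k} = <psi_{j,k}, y>``.  A discontinuity of the
wavelet regression at threshold ``lambda`` can only sit at one of the three
discontinuity positions of a wavelet whose |coefficient| exceeds ``lambda``:

    b_plus = 2^j*k,  b_center = 2^j*(k+1/2),  b_minus = 2^j*(k+1).

The *maxlet transform* stores |d_{j,k}| at ``b_center(j,k)`` (each t > 0 is
the central discontinuity of exactly one wavelet); the *Haar boundary
transform* then turns this layout into per-position breakpoint weights

    b_H[t] = max{ |d_{j,k}| : t in {b_plus, b_center, b_minus} of psi_{j,k} }

with b_H[0] = inf (there is always a boundary before the first position) and
inf wherever a wavelet's support is incomplete (support crossing the end of
the data means its magnitude is unknown, so it must survive any threshold).

Both passes run in O(T) and allocate no auxiliary buffer proportional to T;
the boundary weights later drive the breakpoint array in
:mod:`haarcnv.blocks`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Signal",
    "WaveletIndex",
    "WeightVector",
    "maxlet_transform",
    "haar_boundary_transform",
    "breakpoint_weights",
    "universal_threshold",
    "oracle_wavelet_coefficients",
]


@dataclass(frozen=True)
class Signal:
    """A real-valued track to segment (e.g. windowed differential read depth)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("signal must be a non-empty 1-d array")
        if not np.all(np.isfinite(values)):
            raise ValueError("signal values must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def T(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class WaveletIndex:
    """Scale/shift index of a discrete Haar wavelet and its discontinuities."""

    j: int
    k: int

    def __post_init__(self) -> None:
        if self.j < 1 or self.k < 0:
            raise ValueError("require j >= 1 and k >= 0")

    @property
    def b_plus(self) -> int:
        return (1 << self.j) * self.k

    @property
    def b_center(self) -> int:
        return self.b_plus + (1 << (self.j - 1))

    @property
    def b_minus(self) -> int:
        return self.b_plus + (1 << self.j)


@dataclass
class WeightVector:
    """Per-position non-negative weights with a role tag.

    role "maxlet": position b_center(j,k) holds |d_{j,k}| (inf when the
    wavelet's support is incomplete), position 0 holds inf.
    role "boundary": position t holds the breakpoint weight b_H[t].
    """

    values: np.ndarray
    role: str = field(default="maxlet")

    def __post_init__(self) -> None:
        if self.role not in ("maxlet", "boundary"):
            raise ValueError(f"unknown role {self.role!r}")
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return self.values.size


def maxlet_transform(signal: Signal) -> WeightVector:
    """Absolute Haar detail magnitudes, laid out at central discontinuities.

    Runs the lifting recursion level by level, in place over a single
    length-T buffer: at level j, position b_plus holds the scale coefficient
    c_{j-1,2k} and position b_center holds c_{j-1,2k+1}; they are overwritten
    with c_{j,k} and |d_{j,k}| respectively.  Wavelets whose support crosses
    the end of the data receive inf at their central position.
    """
    if not isinstance(signal, Signal):
        signal = Signal(np.asarray(signal))
    T = signal.T
    buf = signal.values.copy()  # the only length-T buffer; transformed in place
    half = 1
    while half < T:
        step = 2 * half
        centers = np.arange(half, T, step)
        lefts = centers - half
        a = buf[lefts].copy()
        b = buf[centers].copy()
        buf[lefts] = a + b
        buf[centers] = np.abs(a - b) / math.sqrt(step)
        # incomplete support: b_minus = center + half crosses past T
        buf[centers[centers + half > T]] = np.inf
        half = step
    buf[0] = np.inf
    return WeightVector(buf, role="maxlet")


def haar_boundary_transform(weights: WeightVector) -> WeightVector:
    """Turn maxlet magnitudes into breakpoint weights b_H (Eq. for b_H).

    Top-down over scales: each wavelet's magnitude (read at its central
    position, still pristine at that point) is folded by max() into its two
    side-discontinuity positions, which belong to strictly higher scales and
    have already been read.  O(T) total work, no auxiliary buffer.
    """
    if not isinstance(weights, WeightVector):
        raise TypeError("expected a WeightVector")
    if weights.role != "maxlet":
        raise ValueError("haar_boundary_transform expects a maxlet WeightVector")
    buf = weights.values.copy()
    T = buf.size
    # largest scale with a stored center: half = 2^(j-1) < T
    half = 1
    while half * 2 < T:
        half *= 2
    while half >= 1:
        step = 2 * half
        centers = np.arange(half, T, step)
        w = buf[centers]
        lefts = centers - half  # unique within a level
        buf[lefts] = np.maximum(buf[lefts], w)
        rights = centers + half
        inside = rights < T
        buf[rights[inside]] = np.maximum(buf[rights[inside]], w[inside])
        half //= 2
    buf[0] = np.inf
    return WeightVector(buf, role="boundary")


def breakpoint_weights(signal: Signal) -> WeightVector:
    """Convenience composition: boundary weights straight from a signal."""
    return haar_boundary_transform(maxlet_transform(signal))


def universal_threshold(T: int, variance: float) -> float:
    """Universal shrinkage threshold ``sqrt(2 ln T) * sigma``.

    The expected maximum deviation of T i.i.d. centered Gaussians with
    variance ``variance``; coefficients below it are noise with high
    probability.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    return math.sqrt(2.0 * math.log(T) * variance)


def oracle_wavelet_coefficients(signal: Signal) -> list[tuple[WaveletIndex, float]]:
    """Brute-force signed inner products <psi_{j,k}, y>, O(T log T).

    Test oracle only: enumerates every fully supported wavelet and evaluates
    its coefficient by explicit summation.
    """
    if not isinstance(signal, Signal):
        signal = Signal(np.asarray(signal))
    y = signal.values
    T = signal.T
    out: list[tuple[WaveletIndex, float]] = []
    j = 1
    while (1 << (j - 1)) < T:
        width = 1 << j
        k = 0
        while True:
            idx = WaveletIndex(j, k)
            if idx.b_center >= T:
                break
            if idx.b_minus <= T:
                d = (y[idx.b_plus:idx.b_center].sum() - y[idx.b_center:idx.b_minus].sum()) / math.sqrt(width)
                out.append((idx, float(d)))
            k += 1
        j += 1
    return out
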