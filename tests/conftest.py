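import numpy as np
import pytest

from haarcnv import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_wavelet_signal():
    """T=16 signal whose only large Haar coefficients are d_{1,0} and d_{1,7}.

    y = [1,-1,0,...,0,1,-1] gives |d_{1,0}| = |d_{1,7}| = sqrt(2) and every
    other coefficient exactly 0, so any threshold in (0, sqrt(2)) isolates
    those two wavelets.
    """
    y = np.zeros(16)
    y[0], y[1] = 1.0, -1.0
    y[14], y[15] = 1.0, -1.0
    return Signal(y)


def oracle_boundary_weights(signal: Signal) -> np.ndarray:
    """Brute-force per-position breakpoint weights.

    Independent of the maxlet/boundary transforms: enumerates every wavelet
    with a stored central discontinuity, takes |<psi, y>| by explicit
    summation (infinity for incomplete support), and folds it into all of
    the wavelet's discontinuity positions.
    """
    y = signal.values
    T = y.size
    out = np.zeros(T)
    out[0] = np.inf
    j = 1
    while (1 << (j - 1)) < T:
        width = 1 << j
        half = width // 2
        for k in range(0, (T // half) + 1):
            b_plus = width * k
            b_center = b_plus + half
            b_minus = b_plus + width
            if b_center >= T:
                break
            if b_minus <= T:
                w = abs(y[b_plus:b_center].sum() - y[b_center:b_minus].sum()) / np.sqrt(width)
            else:
                w = np.inf
            for p in (b_plus, b_center, b_minus):
                if 0 < p < T:
                    out[p] = max(out[p], w)
        j += 1
    return out
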