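"""Forward-Backward Gibbs sampling of a Gaussian HMM over compressed blocks.

Each sweep redraws the entire latent state path given the current emission
and transition parameters (forward recursion over *blocks*, then backward
sampling), then redraws the parameters from their conjugate posteriors given
the path.  A block of n positions assigned to state s contributes its
Gaussian likelihood through the sufficient statistics (n, sum, sumsq) and a
self-transition factor A[s,s]^(n-1); this is exactly the uncompressed
forward recursion whenever every block is a singleton.

The compression threshold is re-derived every iteration as the universal
threshold sqrt(2 ln T) * sigma_min, where sigma_min^2 is the smallest
emission variance just sampled: low-noise iterations decompress the signal
(more, smaller blocks), high-noise iterations coarsen it.  The first
iteration bootstraps sigma from a median-absolute-successive-difference
(MAD) noise estimate, since no sampled variances exist yet.

Priors: normal-inverse-gamma per state on (mean, variance), Dirichlet on
transition rows and the initial distribution.  States are never relabelled
across iterations; they stay anchored to the data through distinct prior
means placed at quantiles of the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blocks import (
    DEFAULT_CELL_SIZE,
    DEFAULT_MAX_JUMP,
    BreakpointArray,
    IntegralArray,
    SuffStats,
    build_breakpoint_array,
    build_integral_array,
    next_breakpoint,
    query_stats,
)
from .marginals import MarginalRecords, StateRuns, add_run_lengths, init_records
from .wavelets import Signal, breakpoint_weights, universal_threshold

__all__ = [
    "EmissionParams",
    "TransitionModel",
    "Hyperparams",
    "SamplerConfig",
    "SamplerTrace",
    "block_loglik",
    "forward_backward_sample",
    "sample_emissions",
    "sample_transitions",
    "compression_threshold",
    "auto_hyperparams",
    "mad_noise_estimate",
    "run_fbg",
]

_VAR_FLOOR = 1e-8


@dataclass
class EmissionParams:
    """Per-state Gaussian emission mean and variance."""

    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        if self.mu.shape != self.var.shape or self.mu.ndim != 1:
            raise ValueError("mu and var must be 1-d arrays of equal length")
        if np.any(self.var <= 0):
            raise ValueError("emission variances must be positive")

    @property
    def n_states(self) -> int:
        return self.mu.size


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix and initial distribution."""

    A: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if self.pi.shape != (self.A.shape[0],):
            raise ValueError("pi length must match A")
        if np.any(self.A < 0) or np.any(self.pi < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of A must sum to 1")
        if not math.isclose(float(self.pi.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("pi must sum to 1")


@dataclass
class Hyperparams:
    """Conjugate hyperparameters: normal-inverse-gamma + Dirichlet."""

    mu0: np.ndarray      # prior mean per state
    nu: np.ndarray       # prior pseudo-count on the mean
    alpha: np.ndarray    # inverse-gamma shape
    beta: np.ndarray     # inverse-gamma scale
    trans_conc: np.ndarray  # S x S Dirichlet concentrations for transition rows
    init_conc: np.ndarray   # length-S Dirichlet concentration for pi

    def __post_init__(self) -> None:
        for name in ("mu0", "nu", "alpha", "beta", "init_conc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.trans_conc = np.asarray(self.trans_conc, dtype=np.float64)
        if np.any(self.nu <= 0) or np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("nu, alpha, beta must be positive")
        if np.any(self.trans_conc <= 0) or np.any(self.init_conc <= 0):
            raise ValueError("Dirichlet concentrations must be positive")

    @property
    def n_states(self) -> int:
        return self.mu0.size


@dataclass
class SamplerConfig:
    """Run configuration; defaults follow the genome-scale benchmark setup."""

    n_states: int = 8
    iterations: int = 200
    burn_in: int = 1800
    seed: int | None = None
    cell_size: int = DEFAULT_CELL_SIZE
    max_jump: int = DEFAULT_MAX_JUMP
    record_burn_in: bool = False

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class SamplerTrace:
    """Per-iteration diagnostics plus parameter draws."""

    thresholds: list[float] = field(default_factory=list)
    n_blocks: list[int] = field(default_factory=list)
    min_var: list[float] = field(default_factory=list)
    mu: list[np.ndarray] = field(default_factory=list)
    var: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.thresholds)


def block_loglik(stats: SuffStats, mu: float, var: float) -> float:
    """Gaussian log-likelihood of a block from its sufficient statistics."""
    if var <= 0:
        raise ValueError("variance must be positive")
    if stats.n < 1:
        raise ValueError("block must contain at least one position")
    n, s, ss = stats.n, stats.sum, stats.sumsq
    return -0.5 * n * math.log(2.0 * math.pi * var) - (ss - 2.0 * mu * s + n * mu * mu) / (2.0 * var)


def _block_loglik_matrix(n: np.ndarray, s: np.ndarray, ss: np.ndarray,
                         em: EmissionParams) -> np.ndarray:
    """K x S matrix of block log-likelihoods, vectorized over blocks and states."""
    mu = em.mu[None, :]
    var = em.var[None, :]
    n = n[:, None]
    s = s[:, None]
    ss = ss[:, None]
    return -0.5 * n * np.log(2.0 * math.pi * var) - (ss - 2.0 * mu * s + n * mu * mu) / (2.0 * var)


def forward_backward_sample(blocks: list, em: EmissionParams, tm: TransitionModel,
                            rng: np.random.Generator) -> StateRuns:
    """Draw one latent state path over blocks; returns (length, state) runs.

    Forward pass with per-block rescaling: alpha_k(s) is proportional to the
    joint probability of blocks 1..k and state s at block k, with each
    block's emission term A[s,s]^(n_k - 1) * exp(block_loglik).  Backward
    pass samples the last block from alpha_K, then each predecessor
    proportional to alpha_k(s) * A[s, q_{k+1}].
    """
    n = np.array([b.stats.n for b in blocks], dtype=np.int64)
    if n.size == 0:
        raise ValueError("no blocks to sample over")
    s_arr = np.array([b.stats.sum for b in blocks])
    ss_arr = np.array([b.stats.sumsq for b in blocks])
    return _forward_backward_sample_arrays(n, s_arr, ss_arr, em, tm, rng)


def _forward_backward_sample_arrays(n: np.ndarray, s_arr: np.ndarray, ss_arr: np.ndarray,
                                    em: EmissionParams, tm: TransitionModel,
                                    rng: np.random.Generator,
                                    return_alphas: bool = False):
    K = n.size
    S = em.n_states
    logE = _block_loglik_matrix(n, s_arr, ss_arr, em)
    logA_diag = np.log(np.clip(np.diag(tm.A), 1e-300, None))
    logE = logE + (n - 1)[:, None] * logA_diag[None, :]
    A = tm.A
    alphas = np.empty((K, S))
    e0 = np.exp(logE[0] - logE[0].max())
    a = tm.pi * e0
    tot = a.sum()
    if tot <= 0 or not np.isfinite(tot):
        raise FloatingPointError("forward recursion underflowed at block 0")
    alphas[0] = a / tot
    for k in range(1, K):
        ek = np.exp(logE[k] - logE[k].max())
        a = ek * (alphas[k - 1] @ A)
        tot = a.sum()
        if tot <= 0 or not np.isfinite(tot):
            raise FloatingPointError(f"forward recursion underflowed at block {k}")
        alphas[k] = a / tot
    # backward sampling
    states = np.empty(K, dtype=np.int64)
    p = alphas[K - 1] / alphas[K - 1].sum()
    states[K - 1] = _categorical(p, rng)
    for k in range(K - 2, -1, -1):
        p = alphas[k] * A[:, states[k + 1]]
        states[k] = _categorical(p / p.sum(), rng)
    runs: StateRuns = [(int(nk), int(qk)) for nk, qk in zip(n, states)]
    if return_alphas:
        return runs, alphas
    return runs


def _categorical(p: np.ndarray, rng: np.random.Generator) -> int:
    u = rng.random()
    return int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, p.size - 1))


def sample_emissions(assigned_stats: list[SuffStats], hyper: Hyperparams,
                     rng: np.random.Generator) -> EmissionParams:
    """Draw (mu, var) per state from the normal-inverse-gamma posterior.

    States with no assigned data are drawn from the prior unchanged.  Draw
    order is fixed (state 0..S-1, variance then mean) so runs are
    reproducible from the seed.
    """
    S = hyper.n_states
    mu = np.empty(S)
    var = np.empty(S)
    for s in range(S):
        st = assigned_stats[s]
        nu, mu0, alpha, beta = hyper.nu[s], hyper.mu0[s], hyper.alpha[s], hyper.beta[s]
        if st.n > 0:
            n = st.n
            ybar = st.sum / n
            nu_post = nu + n
            mu0_post = (nu * mu0 + st.sum) / nu_post
            alpha_post = alpha + 0.5 * n
            beta_post = (beta + 0.5 * (st.sumsq - st.sum * st.sum / n)
                         + nu * n * (ybar - mu0) ** 2 / (2.0 * nu_post))
        else:
            nu_post, mu0_post, alpha_post, beta_post = nu, mu0, alpha, beta
        sigma2 = beta_post / rng.gamma(alpha_post)
        sigma2 = max(sigma2, _VAR_FLOOR)
        mu[s] = rng.normal(mu0_post, math.sqrt(sigma2 / nu_post))
        var[s] = sigma2
    return EmissionParams(mu, var)


def transition_counts(runs: StateRuns, n_states: int) -> tuple[np.ndarray, np.ndarray]:
    """Transition and initial-state counts implied by a run-length state path.

    Each run of length n contributes n-1 self-transitions; consecutive runs
    contribute one between-run transition; the first run sets the initial
    count.  Totals are T-1 transitions and a single initial count.
    """
    A_counts = np.zeros((n_states, n_states), dtype=np.int64)
    init = np.zeros(n_states, dtype=np.int64)
    init[runs[0][1]] = 1
    prev = None
    for length, state in runs:
        A_counts[state, state] += length - 1
        if prev is not None:
            A_counts[prev, state] += 1
        prev = state
    return A_counts, init


def sample_transitions(A_counts: np.ndarray, init_counts: np.ndarray,
                       hyper: Hyperparams, rng: np.random.Generator) -> TransitionModel:
    """Draw rows of A and pi from their Dirichlet posteriors (fixed order)."""
    S = hyper.n_states
    A = np.empty((S, S))
    for s in range(S):
        A[s] = rng.dirichlet(hyper.trans_conc[s] + A_counts[s])
    pi = rng.dirichlet(hyper.init_conc + init_counts)
    return TransitionModel(A, pi)


def compression_threshold(em: EmissionParams, T: int) -> float:
    """Universal threshold from the smallest sampled emission variance."""
    return universal_threshold(T, float(em.var.min()))


def mad_noise_estimate(signal: Signal) -> float:
    """Noise s.d. from median absolute successive differences.

    Successive differences of a piecewise-constant signal are noise except
    at the few segment boundaries, so their median absolute value divided by
    sqrt(2)*0.6745 is a robust estimate of sigma.
    """
    y = signal.values
    if y.size < 2:
        return math.sqrt(_VAR_FLOOR)
    mad = float(np.median(np.abs(np.diff(y))))
    sigma = mad / (math.sqrt(2.0) * 0.6745)
    if sigma <= 0:
        sigma = math.sqrt(_VAR_FLOOR)
    return sigma


def auto_hyperparams(signal: Signal, n_states: int) -> Hyperparams:
    """Deterministic data-driven priors.

    Prior means sit at evenly spaced quantiles of the signal between the
    0.5th and 99.5th percentiles (the median for a single state), anchoring
    states to distinct data levels; nu = alpha = 1; beta equals the squared
    MAD-based noise estimate so the prior variance scale matches the noise;
    unit Dirichlet concentrations.
    """
    if not isinstance(signal, Signal):
        signal = Signal(np.asarray(signal))
    if signal.T < n_states:
        raise ValueError("need at least as many positions as states")
    if n_states == 1:
        qs = np.array([0.5])
    else:
        qs = np.linspace(0.005, 0.995, n_states)
    mu0 = np.quantile(signal.values, qs)
    sigma = mad_noise_estimate(signal)
    beta = np.full(n_states, max(sigma * sigma, _VAR_FLOOR))
    return Hyperparams(
        mu0=mu0,
        nu=np.ones(n_states),
        alpha=np.ones(n_states),
        beta=beta,
        trans_conc=np.ones((n_states, n_states)),
        init_conc=np.ones(n_states),
    )


def _block_stat_arrays(bpa: BreakpointArray, v: IntegralArray, lam: float):
    """Boundaries and per-block (n, sum, sumsq) arrays at threshold lam."""
    T = bpa.T
    bounds = [0]
    t = next_breakpoint(bpa, 1, lam)
    while t < T:
        bounds.append(t)
        t = next_breakpoint(bpa, t + 1, lam)
    starts = np.asarray(bounds, dtype=np.int64)
    ends = np.append(starts[1:], T)
    K = starts.size
    n = ends - starts
    s_arr = np.empty(K)
    ss_arr = np.empty(K)
    for i in range(K):
        st = query_stats(v, int(starts[i]), int(ends[i]))
        s_arr[i] = st.sum
        ss_arr[i] = st.sumsq
    return starts, ends, n, s_arr, ss_arr


def _merge_runs(runs: StateRuns) -> StateRuns:
    """Coalesce consecutive runs sharing a state before recording.

    Decoded marginal counts are unchanged; the record queue just avoids
    splits at block boundaries that carried no state change.
    """
    merged: StateRuns = []
    for length, state in runs:
        if merged and merged[-1][1] == state:
            merged[-1] = (merged[-1][0] + length, state)
        else:
            merged.append((length, state))
    return merged


def run_fbg(signal: Signal, config: SamplerConfig,
            hyper: Hyperparams | None = None) -> tuple[MarginalRecords, SamplerTrace]:
    """Full dynamically compressed Forward-Backward Gibbs run.

    Builds the breakpoint and integral arrays once; each iteration
    re-blocks the signal at the current threshold, draws a state path,
    redraws parameters from their conjugate posteriors, and updates the
    threshold from the smallest sampled variance.  Marginal state counts are
    recorded after burn-in (or throughout, if requested).
    """
    if not isinstance(signal, Signal):
        signal = Signal(np.asarray(signal))
    T = signal.T
    S = config.n_states
    rng = np.random.default_rng(config.seed)
    if hyper is None:
        hyper = auto_hyperparams(signal, S)
    if hyper.n_states != S:
        raise ValueError("hyperparameter size does not match n_states")

    weights = breakpoint_weights(signal)
    bpa = build_breakpoint_array(weights, config.max_jump)
    v = build_integral_array(signal, config.cell_size)

    # deterministic initialization at prior centers
    sigma0 = mad_noise_estimate(signal)
    em = EmissionParams(hyper.mu0.copy(), np.maximum(hyper.beta, _VAR_FLOOR))
    tm = TransitionModel(
        hyper.trans_conc / hyper.trans_conc.sum(axis=1, keepdims=True),
        hyper.init_conc / hyper.init_conc.sum(),
    )
    lam = universal_threshold(T, sigma0 * sigma0)

    records = init_records(T)
    trace = SamplerTrace()
    total = config.burn_in + config.iterations
    for it in range(total):
        starts, ends, n, s_arr, ss_arr = _block_stat_arrays(bpa, v, lam)
        runs = _forward_backward_sample_arrays(n, s_arr, ss_arr, em, tm, rng)
        # aggregate per-state sufficient statistics of the assignment
        per_state = [[0, 0.0, 0.0] for _ in range(S)]
        for (length, state), s_v, ss_v in zip(runs, s_arr, ss_arr):
            acc = per_state[state]
            acc[0] += length
            acc[1] += s_v
            acc[2] += ss_v
        agg = [SuffStats(int(a[0]), a[1], a[2]) for a in per_state]
        em = sample_emissions(agg, hyper, rng)
        A_counts, init_counts = transition_counts(runs, S)
        tm = sample_transitions(A_counts, init_counts, hyper, rng)
        trace.thresholds.append(lam)
        trace.n_blocks.append(int(n.size))
        trace.min_var.append(float(em.var.min()))
        trace.mu.append(em.mu.copy())
        trace.var.append(em.var.copy())
        if config.record_burn_in or it >= config.burn_in:
            add_run_lengths(records, _merge_runs(runs))
        lam = compression_threshold(em, T)
    return records, trace
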