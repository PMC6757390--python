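"""Model/Results facade over the compressed Gibbs sampler.

:class:`CompressedHMM` is constructed from data (a signal vector, a
:class:`~haarcnv.wavelets.Signal`, or a DataFrame column) plus model
configuration; :meth:`CompressedHMM.fit` runs the dynamically compressed
Forward-Backward Gibbs sampler and returns a :class:`CompressedHMMResults`
carrying posterior marginal state counts, parameter traces, posterior
summaries and segment calls.
"""

from __future__ import annotations

import numpy as np

from .marginals import MarginalRecords, SegmentCall, call_segments
from .sampler import Hyperparams, SamplerConfig, SamplerTrace, auto_hyperparams, run_fbg
from .wavelets import Signal

__all__ = ["CompressedHMM", "CompressedHMMResults"]


class CompressedHMM:
    """Gaussian-emission HMM over a wavelet-compressed signal.

    Parameters
    ----------
    signal : array-like or Signal
        The per-position values to segment (typically a windowed
        differential read-depth track).
    n_states : int
        Number of copy-number states (default 8).
    hyperparams : Hyperparams, optional
        Conjugate priors; derived from the data quantiles and a robust
        noise estimate when omitted.
    """

    def __init__(self, signal, n_states: int = 8, hyperparams: Hyperparams | None = None,
                 cell_size: int | None = None, max_jump: int | None = None):
        self.signal = signal if isinstance(signal, Signal) else Signal(np.asarray(signal, dtype=np.float64))
        self.n_states = n_states
        self.hyperparams = hyperparams if hyperparams is not None \
            else auto_hyperparams(self.signal, n_states)
        self._cell_size = cell_size
        self._max_jump = max_jump

    @classmethod
    def from_dataframe(cls, df, column: str, **kwargs) -> "CompressedHMM":
        return cls(df[column].to_numpy(dtype=np.float64), **kwargs)

    def fit(self, iterations: int = 200, burn_in: int = 1800, seed: int | None = None,
            record_burn_in: bool = False) -> "CompressedHMMResults":
        kwargs = {}
        if self._cell_size is not None:
            kwargs["cell_size"] = self._cell_size
        if self._max_jump is not None:
            kwargs["max_jump"] = self._max_jump
        config = SamplerConfig(n_states=self.n_states, iterations=iterations,
                               burn_in=burn_in, seed=seed,
                               record_burn_in=record_burn_in, **kwargs)
        records, trace = run_fbg(self.signal, config, hyper=self.hyperparams)
        return CompressedHMMResults(self, config, records, trace)


class CompressedHMMResults:
    """Posterior summaries of a fitted compressed HMM."""

    def __init__(self, model: CompressedHMM, config: SamplerConfig,
                 records: MarginalRecords, trace: SamplerTrace):
        self.model = model
        self.config = config
        self.records = records
        self.trace = trace
        recorded = max(len(trace) - (0 if config.record_burn_in else config.burn_in), 1)
        mus = np.asarray(trace.mu[-recorded:])
        vars_ = np.asarray(trace.var[-recorded:])
        #: posterior means of the per-state emission parameters over
        #: recorded iterations
        self.posterior_mu = mus.mean(axis=0)
        self.posterior_mu_sd = mus.std(axis=0, ddof=1) if mus.shape[0] > 1 else np.zeros_like(self.posterior_mu)
        self.posterior_var = vars_.mean(axis=0)

    @property
    def n_iterations_recorded(self) -> int:
        return self.records.iterations

    def modal_states(self) -> np.ndarray:
        """Per-position modal state over the recorded iterations."""
        out = np.empty(self.records.T, dtype=np.int64)
        for start, end, counts in self.records.segments():
            modal = min(counts, key=lambda s: (-counts[s], s))
            out[start:end] = modal
        return out

    def state_occupancy(self) -> np.ndarray:
        """Fraction of positions whose modal state is s, per state."""
        modal = self.modal_states()
        S = self.model.n_states
        return np.bincount(modal, minlength=S)[:S] / modal.size

    def calls(self, min_abs_mean: float = 1.0) -> list[SegmentCall]:
        """Segments whose modal state's posterior-mean |mu| passes the cut."""
        return call_segments(self.records, self.posterior_mu, min_abs_mean)

    def summary(self) -> str:
        lines = [
            "Compressed HMM segmentation (Forward-Backward Gibbs)",
            f"  positions:            {self.records.T}",
            f"  states:               {self.model.n_states}",
            f"  recorded iterations:  {self.n_iterations_recorded}"
            f" (burn-in {self.config.burn_in})",
            f"  marginal segments:    {self.records.n_segments}",
            f"  final threshold:      {self.trace.thresholds[-1]:.4g}",
            f"  mean blocks/iter:     {np.mean(self.trace.n_blocks):.1f}",
            "",
            "  state   post.mean      sd    post.var   occupancy",
        ]
        occ = self.state_occupancy()
        for s in range(self.model.n_states):
            lines.append(f"  {s:5d}  {self.posterior_mu[s]:10.4f}  "
                         f"{self.posterior_mu_sd[s]:7.4f}  {self.posterior_var[s]:9.4f}  "
                         f"{occ[s]:9.3f}")
        return "\n".join(lines)
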