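"""Model/results interface over the Poisson HMM core.

Usage mirrors the fit-then-inspect idiom of statistical modelling
packages::

    model = PoissonHMM(series, k_states=4)
    res = model.fit(seed=7)
    print(res.summary())
    decode = res.decode()
    fc = res.forecast(level=0.95)

A :class:`PoissonHMM` is built from one or many count sequences; ``fit``
runs Baum-Welch EM with random restarts and returns a
:class:`PoissonHMMResults` carrying the estimates, convergence diagnostics
and the decoding/forecasting/rate methods.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import hmm as _hmm
from .rates import state_rates
from .types import CountSeries, DecodeResult, FitTrace, ForecastResult, HmmParams

__all__ = ["PoissonHMM", "PoissonHMMResults"]


class PoissonHMM:
    """K-state hidden Markov model with Poisson emissions for windowed
    asynchrony-event counts.

    Parameters
    ----------
    endog : CountSeries, 1-D array of counts, or a list of either — one
        entry per patient; all sequences share one parameter set.
    k_states : number of latent risk states (default 4).
    window_minutes : indexing window length carried through to saved models.
    """

    def __init__(self, endog, k_states: int = 4, window_minutes: float | None = None):
        if isinstance(endog, (list, tuple)):
            self.sequences = [self._coerce(s) for s in endog]
        else:
            self.sequences = [self._coerce(endog)]
        if not self.sequences:
            raise ValueError("no data supplied")
        self.k_states = int(k_states)
        if window_minutes is None:
            ts = {s.T for s in self.sequences if isinstance(s, CountSeries)}
            window_minutes = ts.pop() if len(ts) == 1 else None
        self.window_minutes = window_minutes

    @staticmethod
    def _coerce(s) -> CountSeries:
        return s if isinstance(s, CountSeries) else CountSeries(x=np.asarray(s))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, count_col: str = "count",
                       exposure_col: str | None = "n_breaths",
                       group_col: str | None = None, k_states: int = 4,
                       T: float = 15.0) -> "PoissonHMM":
        """Build from a long-format frame, one row per window; ``group_col``
        (patient identifier) splits rows into independent sequences."""
        groups = [(None, df)] if group_col is None else df.groupby(group_col, sort=True)
        seqs = []
        for pid, sub in groups:
            n = sub[exposure_col].to_numpy() if exposure_col and exposure_col in sub else None
            if n is not None and np.all(pd.isna(n)):
                n = None
            seqs.append(CountSeries(x=sub[count_col].to_numpy(), n=n, T=T,
                                    patient_id=None if pid is None else str(pid)))
        return cls(seqs, k_states=k_states, window_minutes=T)

    @property
    def nobs(self) -> int:
        return sum(len(s) for s in self.sequences)

    def loglike(self, params: HmmParams) -> float:
        """Total log-likelihood of all sequences under ``params``."""
        return sum(_hmm.forward_backward(params, s).loglik for s in self.sequences)

    def fit(self, n_restarts: int = 10, tol: float = 1e-6, max_iter: int = 500,
            seed: int | None = None) -> "PoissonHMMResults":
        params, trace = _hmm.em_fit(self.sequences, K=self.k_states,
                                    n_restarts=n_restarts, tol=tol,
                                    max_iter=max_iter, seed=seed)
        return PoissonHMMResults(self, params, trace)


class PoissonHMMResults:
    """Fitted Poisson HMM: estimates, diagnostics and derived quantities."""

    def __init__(self, model: PoissonHMM, params: HmmParams, trace: FitTrace):
        self.model = model
        self.params = params
        self.trace = trace
        self.llf = trace.best_loglik if trace.n_restarts else model.loglike(params)
        self._decode_cache: list[DecodeResult] | None = None

    # -- decoding ----------------------------------------------------------
    def decode(self, sequence_index: int | None = None):
        """Smoothed posteriors + Viterbi path, per sequence (cached)."""
        if self._decode_cache is None:
            self._decode_cache = [_hmm.forward_backward(self.params, s)
                                  for s in self.model.sequences]
        if sequence_index is not None:
            return self._decode_cache[sequence_index]
        if len(self._decode_cache) == 1:
            return self._decode_cache[0]
        return self._decode_cache

    @property
    def tspent(self) -> np.ndarray:
        """Viterbi occupancy pooled over all sequences."""
        decs = self._decode_all()
        occ = sum(np.bincount(d.viterbi_path, minlength=self.params.K)
                  for d in decs)
        return occ / occ.sum()

    def _decode_all(self) -> list[DecodeResult]:
        self.decode()
        return self._decode_cache

    # -- forecasting -------------------------------------------------------
    def forecast(self, sequence_index: int = 0, level: float = 0.95
                 ) -> ForecastResult:
        """One-step-ahead forecast past the end of a sequence."""
        return _hmm.forecast_one_step(self.params,
                                      self.model.sequences[sequence_index],
                                      level=level)

    def risk_probability(self, threshold_state: int, sequence_index: int = 0
                         ) -> float:
        """Probability the next window is in state >= threshold_state."""
        fc = self.forecast(sequence_index)
        return _hmm.risk_state_probability(fc, threshold_state)

    # -- derived tables ----------------------------------------------------
    def credible_intervals(self, level: float = 0.95) -> list[tuple[int, int]]:
        return [_hmm.credible_interval(l, level) for l in self.params.lam]

    def rate_table(self, level: float = 0.95, method: str = "gamma"
                   ) -> pd.DataFrame:
        return state_rates(self.params, self._decode_all(),
                           self.model.sequences, level=level, method=method)

    # -- plotting ----------------------------------------------------------
    def plot_decoding(self, sequence_index: int = 0, ax=None):
        """Counts over time coloured by the decoded (Viterbi) state.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        series = self.model.sequences[sequence_index]
        dec = self.decode(sequence_index=sequence_index) \
            if len(self.model.sequences) > 1 else self.decode()
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = np.arange(len(series))
        ax.scatter(t, series.x, c=dec.viterbi_path, cmap="viridis", s=8,
                   vmin=0, vmax=self.params.K - 1)
        for lam in self.params.lam:
            ax.axhline(lam, color="grey", lw=0.5, ls=":")
        ax.set_xlabel(f"window ({self.model.window_minutes or '?'} min)")
        ax.set_ylabel("events per window")
        ax.set_title("Decoded risk states")
        return ax

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        self.params.save(path, window_minutes=self.model.window_minutes)

    # -- reporting ---------------------------------------------------------
    def summary(self, level: float = 0.95) -> str:
        p = self.params
        cis = self.credible_intervals(level)
        ts = self.tspent
        lines = [
            "Poisson Hidden Markov Model Results",
            "=" * 55,
            f"No. sequences: {len(self.model.sequences):>6}    "
            f"No. windows: {self.model.nobs:>8}",
            f"States (K):    {p.K:>6}    Log-likelihood: {self.llf:>12.2f}",
            f"Restarts:      {self.trace.n_restarts:>6}    "
            f"Converged: {str(all(self.trace.converged)):>6}",
            "-" * 55,
            f"{'state':>5} {'lam':>9} {f'{level:.0%} interval':>14} "
            f"{'A[j,j]':>8} {'tspent':>8}",
        ]
        for j in range(p.K):
            lines.append(
                f"{f'z{j + 1}':>5} {p.lam[j]:>9.3f} "
                f"{f'({cis[j][0]}, {cis[j][1]})':>14} "
                f"{p.A[j, j]:>8.3f} {ts[j]:>8.3f}")
        lines.append("=" * 55)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<PoissonHMMResults K={self.params.K} "
                f"nobs={self.model.nobs} llf={self.llf:.2f}>")
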