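"""Core value types shared across the pipeline.

States are indexed 0..K-1 and, after fitting, always ordered so that the
Poisson means are strictly increasing (state 0 = lowest-risk regime).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HmmParams",
    "CountSeries",
    "DecodeResult",
    "ForecastResult",
    "FitTrace",
]


@dataclass
class HmmParams:
    """Parameters of a K-state hidden Markov chain with Poisson emissions.

    Attributes
    ----------
    pi : ndarray, shape (K,)
        Initial state distribution.
    A : ndarray, shape (K, K)
        Row-stochastic transition matrix; ``A[i, j]`` is the probability of
        moving from state ``i`` to state ``j`` between consecutive windows.
    lam : ndarray, shape (K,)
        Per-state Poisson mean (expected event count per window), all > 0.
    """

    pi: np.ndarray
    A: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)

    @property
    def K(self) -> int:
        return self.lam.size

    def validate(self, atol: float = 1e-8) -> "HmmParams":
        if self.pi.shape != (self.K,) or self.A.shape != (self.K, self.K):
            raise ValueError(
                f"inconsistent shapes: pi {self.pi.shape}, A {self.A.shape}, "
                f"lam {self.lam.shape}"
            )
        if not np.isclose(self.pi.sum(), 1.0, atol=atol):
            raise ValueError("initial distribution must sum to 1")
        if np.any(self.pi < -atol):
            raise ValueError("initial distribution has negative entries")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=atol):
            raise ValueError("every transition-matrix row must sum to 1")
        if np.any(self.A < -atol):
            raise ValueError("transition matrix has negative entries")
        if np.any(self.lam <= 0):
            raise ValueError("all Poisson means must be > 0")
        return self

    def canonical(self) -> "HmmParams":
        """Return an equivalent parameter set with states sorted by mean."""
        order = np.argsort(self.lam, kind="stable")
        return HmmParams(
            pi=self.pi[order],
            A=self.A[np.ix_(order, order)],
            lam=self.lam[order],
        )

    def permute(self, order: Sequence[int]) -> "HmmParams":
        order = np.asarray(order)
        return HmmParams(
            pi=self.pi[order],
            A=self.A[np.ix_(order, order)],
            lam=self.lam[order],
        )

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self, window_minutes: float | None = None) -> dict:
        d = {
            "K": int(self.K),
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "lam": self.lam.tolist(),
        }
        if window_minutes is not None:
            d["T_minutes"] = float(window_minutes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        p = cls(pi=np.array(d["pi"]), A=np.array(d["A"]), lam=np.array(d["lam"]))
        if p.K != int(d.get("K", p.K)):
            raise ValueError("stored K inconsistent with parameter arrays")
        return p

    def save(self, path, window_minutes: float | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(window_minutes), fh, indent=1)

    @classmethod
    def load(cls, path) -> "HmmParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CountSeries:
    """Windowed asynchrony-event counts for one patient.

    ``x[k]`` is the number of events in window ``k`` and ``n[k]`` the number
    of respiratory cycles (the exposure) in that window; windows are
    contiguous, half-open intervals of ``T`` minutes.
    """

    x: np.ndarray
    n: np.ndarray | None = None
    T: float = 15.0
    start: pd.Timestamp | None = None
    patient_id: str | None = None
    true_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        if self.x.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.n is not None:
            self.n = np.asarray(self.n)
            if self.n.shape != self.x.shape:
                raise ValueError("exposure n must have the same length as x")
            if np.any(self.n < 0):
                raise ValueError("exposures must be non-negative")
        if self.true_state is not None:
            self.true_state = np.asarray(self.true_state)
        if self.T <= 0:
            raise ValueError("window length T must be positive")
        if self.x.size and (np.any(self.x < 0) or not np.issubdtype(self.x.dtype, np.integer)):
            # accept float arrays that are exactly integral
            xi = np.asarray(self.x)
            if np.any(xi < 0) or not np.allclose(xi, np.round(xi)):
                raise ValueError("counts must be non-negative integers")
            self.x = np.round(xi).astype(np.int64)
        else:
            self.x = self.x.astype(np.int64, copy=False)

    def __len__(self) -> int:
        return self.x.size

    # -- CSV round-trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        start = self.start if self.start is not None else pd.Timestamp("2000-01-01")
        window_start = start + pd.to_timedelta(np.arange(len(self)) * self.T, unit="m")
        df = pd.DataFrame({"window_start": window_start, "count": self.x})
        df["n_breaths"] = self.n if self.n is not None else np.nan
        if self.true_state is not None:
            df["true_state"] = self.true_state
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, T: float | None = None,
                   patient_id: str | None = None) -> "CountSeries":
        ts = pd.to_datetime(df["window_start"])
        if T is None:
            if len(df) < 2:
                raise ValueError("cannot infer window length from <2 windows; pass T")
            T = float((ts.iloc[1] - ts.iloc[0]).total_seconds() / 60.0)
        n = df["n_breaths"].to_numpy() if "n_breaths" in df else None
        if n is not None and np.all(np.isnan(n)):
            n = None
        true_state = df["true_state"].to_numpy() if "true_state" in df else None
        return cls(x=df["count"].to_numpy(), n=n, T=T,
                   start=ts.iloc[0] if len(df) else None,
                   patient_id=patient_id, true_state=true_state)

    @classmethod
    def read_csv(cls, path, T: float | None = None,
                 patient_id: str | None = None) -> "CountSeries":
        return cls.from_frame(pd.read_csv(path), T=T, patient_id=patient_id)


@dataclass
class DecodeResult:
    """State-decoding output for one count series.

    gamma : ndarray (n, K) -- smoothed posterior state probabilities.
    xi_sum : ndarray (K, K) -- expected transition counts summed over time.
    viterbi_path : ndarray (n,) -- jointly most probable state sequence.
    loglik : float -- total data log-likelihood under the parameters.
    tspent : ndarray (K,) -- fraction of windows each state occupies on the
        Viterbi path (the headline time-spent statistic).
    tspent_gamma : ndarray (K,) -- same fraction from mean smoothed posteriors.
    """

    gamma: np.ndarray
    xi_sum: np.ndarray
    viterbi_path: np.ndarray
    loglik: float
    tspent: np.ndarray
    tspent_gamma: np.ndarray


@dataclass
class ForecastResult:
    """One-step-ahead forecast of the next window.

    ``next_state_probs`` is the predicted state distribution for window
    t+1, ``expected_count`` its implied mean event count, and
    ``predictive_interval`` an equal-tailed count interval at ``level``
    from the Poisson-mixture predictive distribution.
    """

    next_state_probs: np.ndarray
    expected_count: float
    predictive_interval: tuple[int, int]
    level: float = 0.95


@dataclass
class FitTrace:
    """EM diagnostics: one log-likelihood trace per random restart."""

    logliks: list = field(default_factory=list)  # list of 1-D arrays
    converged: list = field(default_factory=list)
    best_restart: int = -1

    @property
    def n_restarts(self) -> int:
        return len(self.logliks)

    @property
    def best_loglik(self) -> float:
        return float(self.logliks[self.best_restart][-1])
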