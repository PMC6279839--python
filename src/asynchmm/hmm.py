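"""Poisson hidden Markov model: likelihood, EM, decoding, forecasting.

The observation model is a K-state latent Markov chain where the event
count in window t is Poisson with a state-specific mean::

    z_t ~ Markov(pi, A),        x_t | z_t = j  ~  Poisson(lam_j)

Forward-backward recursions are run in scaled linear space with a
per-window shift of the emission log-probabilities, which keeps them
stable for sequences of 1e5+ windows and means up to 1e3. The Viterbi
recursion runs entirely in log space.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson

from .types import CountSeries, DecodeResult, FitTrace, ForecastResult, HmmParams

__all__ = [
    "poisson_logpmf",
    "forward_backward",
    "viterbi",
    "em_fit",
    "fit_per_sequence_average",
    "credible_interval",
    "forecast_one_step",
    "risk_state_probability",
]

_LAM_FLOOR = 1e-6
_TRANS_FLOOR = 1e-12


def poisson_logpmf(x, lam):
    """Exact Poisson log-pmf via log-gamma; finite for all valid inputs.

    Parameters broadcast; ``x`` must be non-negative integer(s) and
    ``lam`` strictly positive.
    """
    x = np.asarray(x)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("Poisson mean must be > 0")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be non-negative integers")
    xf = x.astype(float)
    out = xf * np.log(lam) - lam - gammaln(xf + 1.0)
    return out if out.ndim else float(out)


def _as_counts(series) -> np.ndarray:
    """Extract a validated 1-D integer count array."""
    if isinstance(series, CountSeries):
        return series.x
    x = np.asarray(series)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("count series must be a non-empty 1-D array")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be non-negative integers")
    return np.round(x).astype(np.int64)


def _emission_logprob(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log P(x_t | z_t = j)."""
    return poisson_logpmf(x[:, None], lam[None, :])


def _forward(params: HmmParams, logB: np.ndarray):
    """Scaled forward pass.

    Returns (alpha_hat, loglik) where alpha_hat[t] is the filtered state
    distribution P(z_t | x_{1:t}).
    """
    n, K = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((n, K))
    c = np.empty(n)
    a = params.pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    AT = params.A
    for t in range(1, n):
        a = (alpha[t - 1] @ AT) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shift.sum())
    return alpha, c, B, shift, loglik


def forward_backward(params: HmmParams, series) -> DecodeResult:
    """Exact smoothed posteriors, expected transitions and log-likelihood.

    Implements the scaled forward-backward recursions; also runs Viterbi so
    the result carries both the smoothed posteriors and the jointly most
    probable path with its per-state occupancy fractions.
    """
    params.validate()
    x = _as_counts(series)
    logB = _emission_logprob(x, params.lam)
    n, K = logB.shape
    alpha, c, B, _, loglik = _forward(params, logB)

    beta = np.empty((n, K))
    beta[-1] = 1.0
    A = params.A
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((K, K))
    for t in range(n - 1):
        xi = (alpha[t][:, None] * A) * (B[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi

    path = viterbi(params, x)
    tspent = np.bincount(path, minlength=K) / n
    return DecodeResult(
        gamma=gamma,
        xi_sum=xi_sum,
        viterbi_path=path,
        loglik=loglik,
        tspent=tspent,
        tspent_gamma=gamma.mean(axis=0),
    )


def viterbi(params: HmmParams, series) -> np.ndarray:
    """Most likely joint state sequence, computed in log space."""
    params.validate()
    x = _as_counts(series)
    logB = _emission_logprob(x, params.lam)
    n, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logpi = np.log(params.pi)
    delta = logpi + logB[0]
    psi = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + logA
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _init_lam(x_all: np.ndarray, K: int, rng: np.random.Generator,
              explore: bool) -> np.ndarray:
    """Initial emission means.

    The first restart clusters log(1+x) with a short 1-D Lloyd pass (counts
    are zero-heavy and span orders of magnitude, so clustering on the log
    scale separates the regimes); later restarts draw random exemplars from
    the distinct observed values, which keeps the restarts diverse enough to
    escape merged-state local optima.
    """
    if explore:
        uniq = np.unique(x_all).astype(float)
        if uniq.size >= K:
            lam = np.sort(rng.choice(uniq, size=K, replace=False))
        else:
            lam = np.sort(rng.uniform(0, max(x_all.max(), 1.0), size=K))
    else:
        y = np.log1p(x_all.astype(float))
        centers = np.sort(np.quantile(y, (np.arange(K) + 0.5) / K))
        assign = np.zeros(y.size, dtype=int)
        for _ in range(25):
            assign = np.argmin(np.abs(y[:, None] - centers[None, :]), axis=1)
            for j in range(K):
                sel = y[assign == j]
                if sel.size:
                    centers[j] = sel.mean()
            centers = np.sort(centers)
        lam = np.array([
            x_all[assign == j].mean() if np.any(assign == j)
            else float(np.expm1(centers[j])) for j in range(K)])
    return lam


def _init_params(x_all: np.ndarray, K: int, rng: np.random.Generator,
                 explore: bool = False) -> HmmParams:
    """Data-driven means with jitter; uniform pi; diagonal-heavy A."""
    lam = _init_lam(x_all, K, rng, explore)
    lam = lam * np.exp(rng.normal(scale=0.15, size=K))
    lam = np.maximum(np.sort(lam), _LAM_FLOOR)
    # break exact ties so states start distinct
    for j in range(1, K):
        if lam[j] <= lam[j - 1]:
            lam[j] = lam[j - 1] * 1.5 + 0.1
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.2 / K) + 0.8 * np.eye(K)
    A /= A.sum(axis=1, keepdims=True)
    return HmmParams(pi=pi, A=A, lam=lam)


def _em_one_restart(xs: list[np.ndarray], params: HmmParams, tol: float,
                    max_iter: int):
    K = params.K
    logliks = []
    converged = False
    for _ in range(max_iter):
        gsum = np.zeros(K)
        gxsum = np.zeros(K)
        xisum = np.zeros((K, K))
        pi_acc = np.zeros(K)
        ll = 0.0
        for x in xs:
            dec = _e_step(params, x)
            gamma, xi, ll_s = dec
            gsum += gamma.sum(axis=0)
            gxsum += gamma.T @ x
            xisum += xi
            pi_acc += gamma[0]
            ll += ll_s
        logliks.append(ll)
        if len(logliks) > 1:
            prev = logliks[-2]
            if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break
        lam = np.maximum(gxsum / np.maximum(gsum, 1e-300), _LAM_FLOOR)
        A = np.maximum(xisum, _TRANS_FLOOR)
        A /= A.sum(axis=1, keepdims=True)
        pi = pi_acc / len(xs)
        pi = np.maximum(pi, 0.0)
        pi /= pi.sum()
        params = HmmParams(pi=pi, A=A, lam=lam)
    else:
        # ran out of iterations after an M-step: record the loglik of the
        # parameters actually returned
        ll = sum(_e_step(params, x)[2] for x in xs)
        logliks.append(ll)
    return params, np.asarray(logliks), converged


def _e_step(params: HmmParams, x: np.ndarray):
    """Gamma, summed xi and loglik without the Viterbi pass (EM inner loop)."""
    logB = _emission_logprob(x, params.lam)
    n, K = logB.shape
    alpha, c, B, _, loglik = _forward(params, logB)
    beta = np.empty((n, K))
    beta[-1] = 1.0
    A = params.A
    xi_sum = np.zeros((K, K))
    for t in range(n - 2, -1, -1):
        w = B[t + 1] * beta[t + 1]
        beta[t] = (A @ w) / c[t + 1]
        xi_sum += (alpha[t][:, None] * A) * w[None, :] / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, xi_sum, loglik


def _as_sequences(series) -> list[np.ndarray]:
    if isinstance(series, (list, tuple)):
        if not series:
            raise ValueError("no sequences supplied")
        return [_as_counts(s) for s in series]
    return [_as_counts(series)]


def em_fit(series, K: int = 4, n_restarts: int = 10, tol: float = 1e-6,
           max_iter: int = 500, seed: int | None = None
           ) -> tuple[HmmParams, FitTrace]:
    """Fit the Poisson HMM by Baum-Welch EM with random restarts.

    ``series`` may be a single count sequence or a list of sequences
    (patients); sequences contribute independent forward-backward passes to
    one shared set of sufficient statistics, so the returned model is the
    pooled fit over all patients. States are re-ordered so the fitted means
    are increasing. Returns the best restart by final log-likelihood
    together with a :class:`FitTrace`.
    """
    xs = _as_sequences(series)
    if K < 1:
        raise ValueError("K must be >= 1")
    x_all = np.concatenate(xs)
    if np.unique(x_all).size < K:
        warnings.warn(
            f"only {np.unique(x_all).size} distinct count values for K={K} "
            "states; fit may be degenerate", RuntimeWarning)
    rng = np.random.default_rng(seed)
    trace = FitTrace()
    best = None
    for r in range(n_restarts):
        params0 = _init_params(x_all, K, rng, explore=r > 0)
        params_r, lls, conv = _em_one_restart(xs, params0, tol, max_iter)
        trace.logliks.append(lls)
        trace.converged.append(conv)
        if best is None or lls[-1] > best[1]:
            best = (params_r, lls[-1], r)
    trace.best_restart = best[2]
    return best[0].canonical().validate(), trace


def fit_per_sequence_average(series: Sequence, K: int = 4, **kwargs
                             ) -> tuple[HmmParams, list[HmmParams]]:
    """Fit each sequence separately and average the canonical parameters.

    Mirrors reporting the average transition probability computed over the
    whole sample of patients; the pooled `em_fit` is the default route.
    """
    seed = kwargs.pop("seed", None)
    ss = np.random.SeedSequence(seed).spawn(len(series))
    fits = [em_fit(s, K=K, seed=int(c.generate_state(1)[0] % (2**31)), **kwargs)[0]
            for s, c in zip(series, ss)]
    A = np.mean([f.A for f in fits], axis=0)
    A /= A.sum(axis=1, keepdims=True)
    pi = np.mean([f.pi for f in fits], axis=0)
    pi /= pi.sum()
    lam = np.mean([f.lam for f in fits], axis=0)
    return HmmParams(pi=pi, A=A, lam=lam).canonical().validate(), fits


# ---------------------------------------------------------------------------
# Intervals and forecasting
# ---------------------------------------------------------------------------

def credible_interval(lam: float, level: float = 0.95) -> tuple[int, int]:
    """Equal-tailed Poisson count interval from the exact quantile function.

    ``lo`` is the smallest integer k with CDF(k) >= (1-level)/2 and ``hi``
    the smallest k with CDF(k) >= 1-(1-level)/2; no normal approximation.
    """
    if lam <= 0:
        raise ValueError("Poisson mean must be > 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lo = int(poisson.ppf(a, lam))
    hi = int(poisson.ppf(1.0 - a, lam))
    return lo, hi


def _mixture_interval(weights: np.ndarray, lam: np.ndarray, level: float
                      ) -> tuple[int, int]:
    """Equal-tailed count interval of a Poisson mixture via its exact CDF."""
    a = (1.0 - level) / 2.0
    kmax = int(max(poisson.ppf(1.0 - a / 10.0, lam).max(), 1)) + 1
    ks = np.arange(kmax + 1)
    cdf = poisson.cdf(ks[:, None], lam[None, :]) @ weights
    lo = int(np.searchsorted(cdf, a, side="left"))
    hi = int(np.searchsorted(cdf, 1.0 - a, side="left"))
    return lo, hi


def forecast_one_step(params: HmmParams, series, level: float = 0.95
                      ) -> ForecastResult:
    """Forecast the next window from the filtered state posterior.

    The filtered posterior at the last observed window is propagated one
    step through the transition matrix; the predictive count distribution
    is the implied Poisson mixture.
    """
    params.validate()
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = _as_counts(series)
    logB = _emission_logprob(x, params.lam)
    alpha, _, _, _, _ = _forward(params, logB)
    next_probs = alpha[-1] @ params.A
    expected = float(next_probs @ params.lam)
    lo, hi = _mixture_interval(next_probs, params.lam, level)
    return ForecastResult(next_state_probs=next_probs, expected_count=expected,
                          predictive_interval=(lo, hi), level=level)


def filtered_forecast_means(params: HmmParams, series) -> np.ndarray:
    """Expected counts for windows 2..n, each from the filter at t-1.

    One forward sweep produces the whole sequence of one-step-ahead mean
    forecasts, aligned with ``x[1:]``.
    """
    params.validate()
    x = _as_counts(series)
    logB = _emission_logprob(x, params.lam)
    alpha, _, _, _, _ = _forward(params, logB)
    preds = (alpha[:-1] @ params.A) @ params.lam
    return preds


def risk_state_probability(forecast: ForecastResult, threshold_state: int) -> float:
    """Probability the next window is at or above a given risk state.

    ``threshold_state`` is a 0-based state index; 0 returns 1 by
    construction (the whole simplex).
    """
    K = forecast.next_state_probs.size
    if not 0 <= threshold_state < K:
        raise ValueError(f"threshold_state must be in [0, {K - 1}]")
    return float(forecast.next_state_probs[threshold_state:].sum())
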