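"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's recursions: likelihoods, posteriors
and best paths are obtained by exhaustive enumeration of all K^n latent
paths, and stationary distributions by eigen-decomposition.
"""
import itertools

import numpy as np
from scipy.special import logsumexp
from scipy.stats import poisson


def enumerate_paths(params, x):
    """(loglik, best_path, posterior_marginals) by exhaustive enumeration."""
    K, n = params.K, len(x)
    logpi = np.log(params.pi)
    logA = np.log(params.A)
    logB = poisson.logpmf(np.asarray(x)[:, None], params.lam[None, :])
    paths = list(itertools.product(range(K), repeat=n))
    logp = np.empty(len(paths))
    for i, path in enumerate(paths):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, n):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        logp[i] = lp
    loglik = logsumexp(logp)
    best = np.array(paths[int(np.argmax(logp))])
    w = np.exp(logp - loglik)
    gamma = np.zeros((n, K))
    for path, wi in zip(paths, w):
        for t, s in enumerate(path):
            gamma[t, s] += wi
    return float(loglik), best, gamma


def stationary_distribution(A):
    """Left eigenvector of A for eigenvalue 1, normalized to sum 1."""
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    return v / v.sum()
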