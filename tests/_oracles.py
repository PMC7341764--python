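"""Closed-form posterior oracles, independent of the MCMC implementation.

With L survivors, dead trees with window probabilities q_j, and a
Beta(a, b) prior, the mortality posterior after marginalizing the latent
window indicators is a mixture of Beta(a + k, b + L) densities over the
number k of in-window deaths, weighted by the Poisson-binomial prior on k
tilted by each component's normalizing constant:

    p(m) ~ prior(m) * (1-m)^L * prod_j (q_j m + 1 - q_j).

For equal q this reduces to binomial weights C(n,k) q^k (1-q)^(n-k).
All moments follow from Beta moments; no sampling involved.
"""

import numpy as np
from scipy.special import betaln, gammaln


def beta_mixture_posterior(qs, n_live, a=1.0, b=1.0):
    """Mixture weights and Beta parameters of the exact marginal posterior."""
    qs = np.asarray(qs, float)
    n = len(qs)
    # Poisson-binomial log pmf over k via iterative convolution
    logw = np.array([0.0])
    for q in qs:
        new = np.full(len(logw) + 1, -np.inf)
        if q < 1.0:
            new[:-1] = np.logaddexp(new[:-1], logw + np.log1p(-q))
        if q > 0.0:
            new[1:] = np.logaddexp(new[1:], logw + np.log(q))
        logw = new
    k = np.arange(n + 1)
    logw = logw + betaln(a + k, b + n_live)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum(), a + k, b + n_live


def posterior_mean(qs, n_live, a=1.0, b=1.0):
    w, alpha, beta = beta_mixture_posterior(qs, n_live, a, b)
    return float(np.sum(w * alpha / (alpha + beta)))


def posterior_quantile(qs, n_live, p, a=1.0, b=1.0, grid_size=20001):
    from scipy.stats import beta as beta_dist

    w, alpha, beta = beta_mixture_posterior(qs, n_live, a, b)
    grid = np.linspace(0.0, 1.0, grid_size)
    cdf = np.sum(w[:, None] * beta_dist.cdf(grid[None, :], alpha[:, None], beta),
                 axis=0)
    return float(np.interp(p, cdf, grid))


def posterior_sd(qs, n_live, a=1.0, b=1.0):
    w, alpha, beta = beta_mixture_posterior(qs, n_live, a, b)
    m1 = alpha / (alpha + beta)
    m2 = alpha * (alpha + 1) / ((alpha + beta) * (alpha + beta + 1))
    mean = np.sum(w * m1)
    return float(np.sqrt(np.sum(w * m2) - mean**2))
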