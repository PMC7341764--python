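"""MCMC convergence diagnostics: Gelman-Rubin PSRF and effective sample size."""

from __future__ import annotations

import numpy as np


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor R-hat.

    Parameters
    ----------
    chains : array of shape (n_chains, n_draws)
        Kept (post burn-in) draws of one scalar parameter.

    Notes
    -----
    With m chains of n draws, W the mean within-chain variance and
    B = n * Var(chain means), the pooled variance estimate is
    ``V = (n-1)/n * W + B/n`` and ``R-hat = sqrt(V / W)``. With zero
    between-chain variance this attains its floor ``sqrt((n-1)/n)``.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 2:
        raise ValueError("Gelman-Rubin requires at least 2 draws per chain")
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    v = (n - 1) / n * w + b / n
    return float(np.sqrt(v / w))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT (lags 0..n-1)."""
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective number of independent draws across all chains.

    Combines within-chain autocovariances with the Gelman-Rubin pooled
    variance and truncates the autocorrelation sum with Geyer's initial
    positive sequence on paired lags.
    """
    chains = np.asarray(chains, float)
    if chains.ndim == 1:
        chains = chains[None, :]
    m, n = chains.shape
    total = m * n
    if np.allclose(chains, chains.flat[0]):
        return float(total)
    acov = np.mean([_autocovariance(c) for c in chains], axis=0)
    w = chains.var(axis=1, ddof=1).mean() if n > 1 else acov[0]
    if m > 1:
        var_plus = (n - 1) / n * w + chains.mean(axis=1).var(ddof=1)
    else:
        var_plus = acov[0] * n / max(n - 1, 1)
    if var_plus == 0:
        return float(total)
    rho = 1.0 - (w - acov) / var_plus
    rho[0] = 1.0
    # Geyer: sum paired autocorrelations while the pair sums stay positive.
    tau = 0.0
    t = 1
    prev_pair = np.inf
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)  # enforce monotone decrease
        tau += pair
        prev_pair = pair
        t += 2
    ess = total / (1.0 + 2.0 * tau)
    return float(min(ess, total))
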