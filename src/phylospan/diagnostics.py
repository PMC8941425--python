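"""MCMC convergence diagnostics: split-chain potential scale reduction and
effective sample size.

The potential scale reduction factor (Gelman–Rubin statistic, "Rhat") compares
between- and within-chain variance; values near 1 indicate the chains have
mixed over the same distribution. Chains are split in half first so that a
single slowly-drifting chain is also detected.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "effective_sample_size"]


class UndefinedStatisticError(ValueError):
    """Raised when a diagnostic is undefined (e.g. zero within-chain variance)."""


def _split_chains(chains: np.ndarray) -> np.ndarray:
    m, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)


def gelman_rubin(chains) -> float:
    """Split-chain potential scale reduction factor for a scalar quantity.

    Parameters
    ----------
    chains : array-like, shape (n_chains, n_draws)
        Post-burn-in draws of one scalar per chain. At least 2 chains with
        at least 10 draws each are required.

    Returns
    -------
    float
        The PSRF; values near 1.0 indicate convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws (2-d array)")
    if chains.shape[1] < 10:
        raise ValueError("need at least 10 draws per chain")
    split = _split_chains(chains)
    m, n = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    if w == 0.0:
        raise UndefinedStatisticError("zero within-chain variance in all chains")
    b_over_n = means.var(ddof=1)  # B/n
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def effective_sample_size(chains) -> float:
    """Effective sample size via Geyer's initial positive sequence estimator.

    Autocovariances are combined across chains (within-chain autocorrelation
    plus between-chain mean dispersion), truncated at the first non-positive
    sum of adjacent autocorrelation pairs.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    means = chains.mean(axis=1, keepdims=True)
    centered = chains - means
    # FFT autocovariance per chain
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :n].real
    acov /= n
    w = acov[:, 0].mean()
    if m > 1:
        b_over_n = chains.mean(axis=1).var(ddof=1)
        var_hat = (n - 1) / n * w + b_over_n
    else:
        var_hat = acov[:, 0].mean()
    if var_hat == 0:
        return float(m * n)
    rho = 1.0 - (w - acov.mean(axis=0)) / var_hat  # combined autocorrelation
    # Geyer initial positive sequence on pair sums rho[2k]+rho[2k+1]
    tau = 1.0
    for k in range(1, (n - 1) // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        tau += 2 * pair
    return float(m * n / max(tau, 1.0))
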