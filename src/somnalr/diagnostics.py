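"""Convergence diagnostics: split potential-scale-reduction and effective
sample size.

Both operate on a (n_chains, n_draws) array of post-warmup draws of one
scalar parameter.  ``split_rhat`` halves every chain before comparing
within- to between-chain variance, so a trending single chain is caught
even with few chains.  ``effective_sample_size`` truncates the pooled
autocorrelation sequence with Geyer's initial-positive-sequence rule.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_rhat", "effective_sample_size"]


def _split_chains(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1] // 2
    if n < 2:
        raise ValueError("need at least 4 draws per chain")
    return np.vstack([x[:, :n], x[:, n : 2 * n]])


def _is_degenerate(W: float, s: np.ndarray) -> bool:
    # relative tolerance: a constant chain's variance is rounding noise
    return W <= 1e-14 * max(float(np.mean(s**2)), np.finfo(float).tiny)


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Returns 1.0 by convention when the draws carry no variance at all
    (degenerate chains).
    """
    s = _split_chains(x)
    m, n = s.shape
    chain_means = s.mean(axis=1)
    W = s.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if _is_degenerate(W, s) and _is_degenerate(B / n, s):
        return 1.0
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT."""
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-based ESS of pooled split chains.

    Chain-averaged autocovariances are combined with the between-chain
    variance into lag correlations rho_t; the sum is truncated at the first
    lag pair (rho_{2k} + rho_{2k+1}) that turns negative and the pair sums
    are forced monotone non-increasing.  Constant chains return 0 by
    convention.
    """
    s = _split_chains(x)
    m, n = s.shape
    W = s.var(axis=1, ddof=1).mean()
    B_over_n = s.mean(axis=1).var(ddof=1)
    if _is_degenerate(W, s) and _is_degenerate(B_over_n, s):
        return 0.0
    B = n * B_over_n
    var_plus = (n - 1) / n * W + B / n
    if var_plus == 0:
        return 0.0
    acov = np.mean([_autocovariance(row) for row in s], axis=0)
    rho = 1.0 - (W - acov) / var_plus
    # Geyer initial positive + monotone sequence on pair sums
    prev_pair = np.inf
    t = 0
    total = 0.0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        total += pair
        t += 2
    tau = max(2.0 * total - 1.0, 1.0 / (m * n))
    return float(m * n / tau)
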