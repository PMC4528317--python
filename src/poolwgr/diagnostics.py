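"""MCMC diagnostics: effective sample size and the truncated-normal mean.

The mean of the left-truncated Normal N(m, d^2)+ is the "typical" deviation of
population-specific marker effects from the overall effects and serves as the
population-divergence metric of the multilevel model.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["truncated_normal_mean", "effective_sample_size"]


def truncated_normal_mean(m, d):
    """Mean of the Normal(m, d^2) distribution left-truncated at zero.

    Closed form: m + d * phi(m/d) / Phi(m/d), with phi/Phi the standard Normal
    pdf/cdf.  Accepts scalars or arrays; requires d > 0.
    """
    m = np.asarray(m, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    alpha = m / d
    out = m + d * np.exp(stats.norm.logpdf(alpha) - stats.norm.logcdf(alpha))
    return float(out) if out.ndim == 0 else out


def effective_sample_size(chain) -> float:
    """Effective sample size of a single MCMC chain.

    ESS = n / (1 + 2 * sum_t rho_t), with empirical autocorrelations summed by
    Geyer's initial-positive-sequence rule (pairs rho_{2t} + rho_{2t+1} are
    accumulated while positive).  The estimate is capped at n.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("chain must have at least 10 samples")
    x = x - x.mean()
    var0 = float(np.dot(x, x)) / n
    if var0 == 0.0 or not np.isfinite(var0):
        raise ValueError("ESS is undefined for a constant chain")
    # autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence over pairs (rho_0 + rho_1), (rho_2 + rho_3), ...
    tau = 0.0
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        t += 2
    tau -= 1.0  # rho_0 = 1 counted twice in the pair sum
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))
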