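"""Independent numeric oracles for the MCMC samplers.

Dense-grid quadrature of the exact single-marker posteriors.  These
implementations share no code with the samplers: conjugate layers are reduced
analytically (scaled-inv-chi^2 mixed into t densities, the intercept
marginalized by Sherman-Morrison) and every remaining dimension is integrated
on an explicit grid.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def _loglik_beta0_marginal(resid: np.ndarray, sigma_e2, beta0_var: float) -> np.ndarray:
    """log N(resid; beta0 1, sigma_e2 I) marginalized over beta0 ~ N(0, V).

    Marginal covariance sigma_e2 I + V 11'; log-density via Sherman-Morrison.
    ``sigma_e2`` may be an array (broadcast over a grid).
    """
    n = resid.size
    s2 = np.asarray(sigma_e2, dtype=float)
    rr = float(resid @ resid)
    rs = float(resid.sum())
    logdet = n * np.log(s2) + np.log1p(n * beta0_var / s2)
    quad = rr / s2 - beta0_var * rs**2 / (s2 * (s2 + n * beta0_var))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def bayesa_posterior_mean_effect(
    z: np.ndarray,
    y: np.ndarray,
    df: float = 4.001,
    s2_shape: float = 1.1,
    s2_rate: float = 1.1,
    beta0_var: float = 1e6,
    n_u: int = 2001,
    u_max: float = 4.0,
) -> float:
    """E[u | y] for single-marker BayesA by dense-grid quadrature.

    Prior of u given S^2 is Student-t (sigma_k^2 integrated analytically);
    S^2 ~ Gamma(shape, rate) and sigma_e^2 (improper (sigma_e^2)^(-1/2) prior)
    are integrated on log grids; beta0 in closed form.
    """
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    u = np.linspace(-u_max, u_max, n_u)

    # prior density of u: scale mixture of t over S^2 ~ Gamma
    lt = np.linspace(np.log(1e-8), np.log(50.0), 1200)
    S2 = np.exp(lt)
    w_s2 = stats.gamma.pdf(S2, a=s2_shape, scale=1.0 / s2_rate) * S2  # log-grid Jacobian
    s = np.sqrt(S2)
    t_dens = stats.t.pdf(u[:, None] / s[None, :], df=df) / s[None, :]
    prior_u = np.trapezoid(t_dens * w_s2[None, :], lt, axis=1)

    # likelihood of u: residual variance integrated on a log grid
    lv = np.linspace(np.log(1e-7), np.log(1e5), 1600)
    s2e = np.exp(lv)
    loglik = np.empty(u.size)
    for i, ui in enumerate(u):
        ll = _loglik_beta0_marginal(y - z * ui, s2e, beta0_var)
        # improper prior (sigma_e^2)^(-1/2), Jacobian sigma_e^2 for the log grid
        ll = ll - 0.5 * lv + lv
        mx = ll.max()
        loglik[i] = mx + np.log(np.trapezoid(np.exp(ll - mx), lv))
    w = prior_u * np.exp(loglik - loglik.max())
    return float(np.trapezoid(u * w, u) / np.trapezoid(w, u))


def multilevel_posterior_mean_effect(
    z: np.ndarray,
    y: np.ndarray,
    df: float = 4.001,
    hyper_lo: float = 0.001,
    hyper_hi: float = 0.5,
    sigma_e_hi: float = 1.0,
    beta0_var: float = 1e6,
    n_u: int = 801,
    u_max: float = 4.0,
) -> float:
    """E[u_j | y] for the single-population, single-marker multilevel model.

    The hierarchy is reduced from the outside in, each stage a 1-2D grid
    integral: prior p(gamma) over Uniform (m, d); prior p(u) as a t mixture
    over Uniform S^2; p(u_j) as the Normal(u, gamma^2) mixture of the two;
    likelihood of u_j with beta0 analytic and sigma_e ~ Uniform(0, 1) on a
    grid.
    """
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    uj = np.linspace(-u_max, u_max, n_u)
    du = uj[1] - uj[0]

    # p(gamma): truncated-Normal mixture over uniform m, d
    gamma = np.concatenate(
        [np.linspace(1e-5, 0.3, 400, endpoint=False), np.linspace(0.3, 3.5, 220)]
    )
    mg = np.linspace(hyper_lo, hyper_hi, 100)
    dg = np.linspace(hyper_lo, hyper_hi, 100)
    dens = np.zeros_like(gamma)
    for im in range(mg.size):
        tn = stats.norm.pdf((gamma[None, :] - mg[im]) / dg[:, None]) / (
            dg[:, None] * stats.norm.cdf(mg[im] / dg[:, None])
        )
        dens += np.trapezoid(tn, dg, axis=0)
    p_gamma = dens / np.trapezoid(dens, gamma)

    # p(u): t mixture over uniform S^2
    S2 = np.linspace(hyper_lo, hyper_hi, 300)
    s = np.sqrt(S2)
    t_dens = stats.t.pdf(uj[:, None] / s[None, :], df=df) / s[None, :]
    p_u = np.trapezoid(t_dens, S2, axis=1)
    p_u /= np.trapezoid(p_u, uj)

    # p(u_j) = int N(u_j; u, gamma^2) p(u) du p(gamma) dgamma
    kern = np.empty((gamma.size, uj.size))
    for ig, g in enumerate(gamma):
        if g < 3 * du:
            kern[ig] = p_u  # near-delta kernel: convolution is the identity
        else:
            K = stats.norm.pdf((uj[:, None] - uj[None, :]) / g) / g
            kern[ig] = np.trapezoid(K * p_u[None, :], uj, axis=1)
    p_uj = np.trapezoid(kern * p_gamma[:, None], gamma, axis=0)

    # likelihood with sigma_e ~ Uniform(0, sigma_e_hi)
    se = np.linspace(1e-4, sigma_e_hi, 800)
    loglik = np.empty(uj.size)
    for i, ui in enumerate(uj):
        ll = _loglik_beta0_marginal(y - z * ui, se**2, beta0_var)
        mx = ll.max()
        loglik[i] = mx + np.log(np.trapezoid(np.exp(ll - mx), se))
    w = p_uj * np.exp(loglik - loglik.max())
    return float(np.trapezoid(uj * w, uj) / np.trapezoid(w, uj))


def truncated_normal_mean_quadrature(m: float, d: float, n: int = 400_000) -> float:
    """Mean of N(m, d^2)+ by direct numeric integration of x * pdf on (0, inf)."""
    hi = max(m, 0.0) + 12 * d
    x = np.linspace(0.0, hi, n)
    logpdf = stats.norm.logpdf(x, loc=m, scale=d)
    w = np.exp(logpdf - logpdf.max())  # shifted to dodge tail underflow
    return float(np.trapezoid(x * w, x) / np.trapezoid(w, x))
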