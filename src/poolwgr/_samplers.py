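"""Numba-compiled MCMC kernels for the whole-genome regression samplers.

Two single-chain samplers are implemented:

* :func:`bayesa_chain` — BayesA (conjugate Gibbs throughout): Normal full
  conditionals for the intercept and marker effects, scaled-inverse-chi^2 for
  the per-marker effect variances and the residual variance, and either a
  conjugate Gamma update or a bounded slice update for the scale
  hyperparameter S^2.

* :func:`multilevel_chain` — the hierarchical partial-pooling model
  (Metropolis-within-Gibbs): conjugate Normal updates for the intercept, the
  population-specific effects u_jk and the overall effects u_k; conjugate
  scaled-inverse-chi^2 for sigma_k^2; univariate slice sampling (stepping-out
  with shrinkage) for gamma_k, m, d, S^2 and sigma_e, whose priors
  (truncated Normal, bounded Uniforms) are not conjugate.

The scan order is fixed (parameter by parameter, markers in column order) and
all randomness flows through numba's own global RNG seeded once at chain
start, so a chain is bit-reproducible for a given seed.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _log_phi_ratio_cdf(x):
    """log Phi(x) for the truncation normalizer (x = m/d >= 0 in practice)."""
    return math.log(0.5 * math.erfc(-x / _SQRT2))


@njit(cache=True)
def _logf(which, x, a1, a2, a3, a4):
    """Unnormalized log full-conditional densities for the scalar slice updates.

    which = 1: m.        a1 = K_active, a2 = sum gamma_k, a3 = sum gamma_k^2,
               a4 = d.
    which = 2: d.        a1 = K_active, a2 = sum (gamma_k - m)^2, a3 = m.
    which = 3: S^2.      a1 = K_active * nu / 2, a2 = (nu / 2) * sum 1/sigma_k^2.
    which = 4: sigma_e.  a1 = n (observations), a2 = residual sum of squares.
    """
    if which == 1:
        return -(a3 - 2.0 * x * a2 + a1 * x * x) / (2.0 * a4 * a4) - a1 * _log_phi_ratio_cdf(
            x / a4
        )
    elif which == 2:
        return -a1 * math.log(x) - a2 / (2.0 * x * x) - a1 * _log_phi_ratio_cdf(a3 / x)
    elif which == 3:
        return a1 * math.log(x) - a2 * x
    else:
        return -a1 * math.log(x) - a2 / (2.0 * x * x)


@njit(cache=True)
def _slice_update(which, x0, lo, hi, w, max_step, a1, a2, a3, a4):
    """One univariate slice-sampling transition (Neal 2003, stepping out)."""
    logy = _logf(which, x0, a1, a2, a3, a4) + math.log(np.random.random())
    u = np.random.random()
    left = x0 - w * u
    right = left + w
    j = int(np.random.random() * max_step)
    k = max_step - 1 - j
    while j > 0 and left > lo and _logf(which, left, a1, a2, a3, a4) > logy:
        left -= w
        j -= 1
    while k > 0 and right < hi and _logf(which, right, a1, a2, a3, a4) > logy:
        right += w
        k -= 1
    if left < lo:
        left = lo
    if right > hi:
        right = hi
    while True:
        x1 = left + np.random.random() * (right - left)
        if x1 > lo and x1 < hi and _logf(which, x1, a1, a2, a3, a4) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


@njit(cache=True)
def _log_gamma_marginal(g, s_arr, zz_arr, nk, sige2, m, d):
    """Log conditional of gamma_k with the specific effects u_jk integrated out.

    Per estimated population j (arrays of length nk), the marginal of the
    partial residual r_j (current residual with u_jk added back, centered at
    z_jk u_k) is N(0, sigma_e^2 I + gamma^2 z_jk z_jk'); by the matrix
    determinant lemma its log density reduces to the scalars
    s_j = z_jk' r_j - zz_j u_k and zz_j = z_jk' z_jk.  The truncated-Normal
    prior N(m, d^2)+ contributes its kernel (the normalizer is constant in
    gamma).
    """
    g2 = g * g
    out = -((g - m) ** 2) / (2.0 * d * d)
    for j in range(nk):
        denom = sige2 + g2 * zz_arr[j]
        out += 0.5 * g2 * s_arr[j] * s_arr[j] / (sige2 * denom)
        out -= 0.5 * math.log(1.0 + g2 * zz_arr[j] / sige2)
    return out


@njit(cache=True)
def _slice_gamma(x0, w, max_step, s_arr, zz_arr, nk, sige2, m, d):
    """Slice-sampling transition for gamma_k under the collapsed conditional."""
    logy = _log_gamma_marginal(x0, s_arr, zz_arr, nk, sige2, m, d) + math.log(
        np.random.random()
    )
    u = np.random.random()
    left = x0 - w * u
    right = left + w
    j = int(np.random.random() * max_step)
    k = max_step - 1 - j
    while j > 0 and left > 0.0 and _log_gamma_marginal(left, s_arr, zz_arr, nk, sige2, m, d) > logy:
        left -= w
        j -= 1
    while k > 0 and _log_gamma_marginal(right, s_arr, zz_arr, nk, sige2, m, d) > logy:
        right += w
        k -= 1
    if left < 0.0:
        left = 0.0
    while True:
        x1 = left + np.random.random() * (right - left)
        if x1 > 0.0 and _log_gamma_marginal(x1, s_arr, zz_arr, nk, sige2, m, d) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


@njit(cache=True)
def bayesa_chain(
    Z,
    y,
    n_samples,
    burn_in,
    thin,
    seed,
    df,
    s2_uniform,
    s2_gamma_shape,
    s2_gamma_rate,
    s2_lo,
    s2_hi,
    beta0_var,
    slice_w,
    max_step,
):
    """Single-chain BayesA Gibbs sampler on standardized phenotypes.

    Returns retained (post burn-in, thinned) samples of beta0, the marker
    effects u_k, the per-marker variances sigma_k^2, S^2 and sigma_e^2.
    """
    np.random.seed(seed)
    n, K = Z.shape
    zz = np.empty(K)
    for k in range(K):
        s = 0.0
        for i in range(n):
            s += Z[i, k] * Z[i, k]
        zz[k] = s

    beta0 = 0.0
    u = np.zeros(K)
    sig2 = np.full(K, 0.05)
    S2 = 0.05
    sige2 = 0.25

    e = y.copy()  # residuals y - mu with all effects zero

    out_beta0 = np.empty(n_samples)
    out_u = np.empty((n_samples, K))
    out_sig2 = np.empty((n_samples, K))
    out_S2 = np.empty(n_samples)
    out_sige2 = np.empty(n_samples)

    total = burn_in + n_samples * thin
    kept = 0
    for it in range(total):
        # intercept: Normal full conditional
        prec = n / sige2 + 1.0 / beta0_var
        s = 0.0
        for i in range(n):
            s += e[i]
        mean = ((s + n * beta0) / sige2) / prec
        newb = mean + np.random.standard_normal() / math.sqrt(prec)
        delta = newb - beta0
        for i in range(n):
            e[i] -= delta
        beta0 = newb

        # marker effects: Normal full conditionals, column order
        for k in range(K):
            uk = u[k]
            if zz[k] <= 0.0:
                # centered-monomorphic column: full conditional is the prior
                u[k] = math.sqrt(sig2[k]) * np.random.standard_normal()
                continue
            rhs = zz[k] * uk
            for i in range(n):
                rhs += Z[i, k] * e[i]
            prec = zz[k] / sige2 + 1.0 / sig2[k]
            mean = (rhs / sige2) / prec
            un = mean + np.random.standard_normal() / math.sqrt(prec)
            d = un - uk
            for i in range(n):
                e[i] -= Z[i, k] * d
            u[k] = un

        # per-marker variances: scaled-inv-chi^2(df + 1, (df S2 + u_k^2)/(df + 1))
        inv_sum = 0.0
        for k in range(K):
            sig2[k] = (df * S2 + u[k] * u[k]) / np.random.chisquare(df + 1.0)
            inv_sum += 1.0 / sig2[k]

        # scale hyperparameter
        if s2_uniform:
            S2 = _slice_update(
                3, S2, s2_lo, s2_hi, slice_w, max_step, 0.5 * K * df, 0.5 * df * inv_sum, 0.0, 0.0
            )
        else:
            shape = s2_gamma_shape + 0.5 * K * df
            rate = s2_gamma_rate + 0.5 * df * inv_sum
            S2 = np.random.gamma(shape, 1.0 / rate)

        # residual variance: improper scaled-inv-chi^2(-1, 0) prior
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sige2 = sse / np.random.chisquare(n - 1.0)

        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            out_beta0[kept] = beta0
            for k in range(K):
                out_u[kept, k] = u[k]
                out_sig2[kept, k] = sig2[k]
            out_S2[kept] = S2
            out_sige2[kept] = sige2
            kept += 1

        if (it + 1) % 1000 == 0:
            # refresh residuals to cancel accumulated float drift
            for i in range(n):
                s = y[i] - beta0
                for k in range(K):
                    s -= Z[i, k] * u[k]
                e[i] = s

    return out_beta0, out_u, out_sig2, out_S2, out_sige2


@njit(cache=True)
def multilevel_chain(
    Z,
    y,
    pop_start,
    pop_end,
    est,
    n_samples,
    burn_in,
    thin,
    seed,
    df,
    hyp_lo,
    hyp_hi,
    sige_hi,
    beta0_var,
    pin_gamma,
    slice_w,
    max_step,
):
    """Metropolis-within-Gibbs sampler for the multilevel partial-pooling model.

    Rows of ``Z``/``y`` must be grouped contiguously by population
    (``pop_start[j]:pop_end[j]`` is population j's row block).  ``est`` is the
    populations x markers indicator of which specific effects u_jk are
    estimated (marker polymorphic in that population); the rest are pinned to
    zero and excluded from every hierarchical conditional.  ``pin_gamma > 0``
    fixes all gamma_k at that value and skips the gamma/m/d updates
    (diagnostic mode).
    """
    np.random.seed(seed)
    n, K = Z.shape
    P = pop_start.size

    # active markers: estimated in at least one population
    nk = np.zeros(K, dtype=np.int64)
    for k in range(K):
        c = 0
        for j in range(P):
            if est[j, k] != 0:
                c += 1
        nk[k] = c
    K_active = 0
    for k in range(K):
        if nk[k] > 0:
            K_active += 1

    # per-population column squared norms
    zzj = np.zeros((P, K))
    for j in range(P):
        for k in range(K):
            s = 0.0
            for i in range(pop_start[j], pop_end[j]):
                s += Z[i, k] * Z[i, k]
            zzj[j, k] = s

    beta0 = 0.0
    u = np.zeros(K)  # overall effects u_k
    ujk = np.zeros((P, K))  # specific effects
    sig2 = np.full(K, 0.05)
    gamma = np.full(K, 0.05)
    if pin_gamma > 0.0:
        for k in range(K):
            gamma[k] = pin_gamma
    m = 0.05
    d = 0.05
    S2 = 0.05
    sige = 0.5

    e = y.copy()
    qbuf = np.empty(n)
    tbuf = np.empty(P)
    zzbuf = np.empty(P)
    sbuf = np.empty(P)
    jbuf = np.empty(P, dtype=np.int64)

    out_beta0 = np.empty(n_samples)
    out_u = np.empty((n_samples, K))
    out_ujk = np.empty((n_samples, P, K))
    out_sig2 = np.empty((n_samples, K))
    out_gamma = np.empty((n_samples, K))
    out_m = np.empty(n_samples)
    out_d = np.empty(n_samples)
    out_S2 = np.empty(n_samples)
    out_sige = np.empty(n_samples)

    total = burn_in + n_samples * thin
    kept = 0
    for it in range(total):
        sige2 = sige * sige

        # intercept
        prec = n / sige2 + 1.0 / beta0_var
        s = 0.0
        for i in range(n):
            s += e[i]
        mean = ((s + n * beta0) / sige2) / prec
        newb = mean + np.random.standard_normal() / math.sqrt(prec)
        delta = newb - beta0
        for i in range(n):
            e[i] -= delta
        beta0 = newb

        # marker blocks in column order: blocked (gamma_k, {u_jk}) draw —
        # gamma_k from its collapsed conditional (u_jk integrated out), then
        # the u_jk from their Normal full conditionals — followed by u_k and
        # sigma_k^2.  The blocking avoids the funnel degeneracy of the
        # centered hierarchy, in which gamma_k decouples from the data.
        inv_sum = 0.0
        for k in range(K):
            if nk[k] == 0:
                continue
            # partial-residual projections t_j = z_jk' (e_j + z_jk u_jk)
            c = 0
            for j in range(P):
                if est[j, k] == 0:
                    continue
                t = zzj[j, k] * ujk[j, k]
                for i in range(pop_start[j], pop_end[j]):
                    t += Z[i, k] * e[i]
                tbuf[c] = t
                zzbuf[c] = zzj[j, k]
                jbuf[c] = j
                c += 1

            if pin_gamma <= 0.0:
                for a in range(c):
                    sbuf[a] = tbuf[a] - zzbuf[a] * u[k]
                gamma[k] = _slice_gamma(
                    gamma[k], slice_w, max_step, sbuf, zzbuf, c, sige2, m, d
                )
            g2 = gamma[k] * gamma[k]

            # overall effect u_k from its collapsed conditional (u_jk
            # integrated out; Sherman-Morrison): the data inform u_k directly,
            # which keeps the rigid-coupling limit gamma_k -> 0 well mixed.
            A = 1.0 / sig2[k]
            B = 0.0
            for a in range(c):
                denom = sige2 + g2 * zzbuf[a]
                A += zzbuf[a] / denom
                B += tbuf[a] / denom
            u[k] = B / A + np.random.standard_normal() / math.sqrt(A)

            # specific effects u_jk | gamma_k, u_k, data
            for a in range(c):
                j = jbuf[a]
                old = ujk[j, k]
                prec = zzbuf[a] / sige2 + 1.0 / g2
                mean = (tbuf[a] / sige2 + u[k] / g2) / prec
                new = mean + np.random.standard_normal() / math.sqrt(prec)
                dlt = new - old
                for i in range(pop_start[j], pop_end[j]):
                    e[i] -= Z[i, k] * dlt
                ujk[j, k] = new

            # sigma_k^2 | u_k (one observation)
            sig2[k] = (df * S2 + u[k] * u[k]) / np.random.chisquare(df + 1.0)
            inv_sum += 1.0 / sig2[k]

        # m, d | {gamma_k}  (Uniform(hyp_lo, hyp_hi) priors; slice)
        if pin_gamma <= 0.0:
            gsum = 0.0
            gsq = 0.0
            for k in range(K):
                if nk[k] > 0:
                    gsum += gamma[k]
                    gsq += gamma[k] * gamma[k]
            m = _slice_update(
                1, m, hyp_lo, hyp_hi, slice_w, max_step, float(K_active), gsum, gsq, d
            )
            ssm = gsq - 2.0 * m * gsum + K_active * m * m
            d = _slice_update(2, d, hyp_lo, hyp_hi, slice_w, max_step, float(K_active), ssm, m, 0.0)

        # group scale move: Metropolis proposal rescaling every deviation
        # u_jk - u_k, every gamma_k, m and d by a common factor c.  The
        # deviation and gamma priors are scale-equivariant, so the acceptance
        # ratio reduces to the data-likelihood change plus 2 log c from the
        # Jacobian; the move slides the whole hierarchy along its weakly
        # identified scale direction, which the one-at-a-time updates only
        # traverse by a slow random walk.
        if pin_gamma <= 0.0 and K_active > 0:
            for j in range(P):
                for i in range(pop_start[j], pop_end[j]):
                    q = 0.0
                    for k in range(K):
                        if est[j, k] != 0:
                            q += Z[i, k] * (ujk[j, k] - u[k])
                    qbuf[i] = q
            qq = 0.0
            eq = 0.0
            for i in range(n):
                qq += qbuf[i] * qbuf[i]
                eq += e[i] * qbuf[i]
            ctot = 1.0
            mm = m
            dd = d
            for _rep in range(10):
                lc = (np.random.random() * 2.0 - 1.0) * 0.3
                c = math.exp(lc)
                if (
                    mm * c < hyp_lo
                    or mm * c > hyp_hi
                    or dd * c < hyp_lo
                    or dd * c > hyp_hi
                ):
                    continue
                dsse = -2.0 * (c - 1.0) * eq + (c - 1.0) ** 2 * qq
                if math.log(np.random.random()) < -dsse / (2.0 * sige2) + 2.0 * lc:
                    eq = c * (eq - (c - 1.0) * qq)
                    qq = c * c * qq
                    mm *= c
                    dd *= c
                    ctot *= c
            if ctot != 1.0:
                m = mm
                d = dd
                for k in range(K):
                    if nk[k] > 0:
                        gamma[k] *= ctot
                for j in range(P):
                    for k in range(K):
                        if est[j, k] != 0:
                            ujk[j, k] = u[k] + ctot * (ujk[j, k] - u[k])
                for i in range(n):
                    e[i] -= (ctot - 1.0) * qbuf[i]

        # S^2 | {sigma_k^2}  (Uniform prior; slice)
        S2 = _slice_update(
            3, S2, hyp_lo, hyp_hi, slice_w, max_step, 0.5 * K_active * df, 0.5 * df * inv_sum, 0.0, 0.0
        )

        # sigma_e | residuals  (Uniform(0, sige_hi) prior on the SD; slice)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sige = _slice_update(4, sige, 0.0, sige_hi, slice_w, max_step, float(n), sse, 0.0, 0.0)

        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            out_beta0[kept] = beta0
            for k in range(K):
                out_u[kept, k] = u[k]
                out_sig2[kept, k] = sig2[k]
                out_gamma[kept, k] = gamma[k]
                for j in range(P):
                    out_ujk[kept, j, k] = ujk[j, k]
            out_m[kept] = m
            out_d[kept] = d
            out_S2[kept] = S2
            out_sige[kept] = sige
            kept += 1

        if (it + 1) % 1000 == 0:
            # refresh residuals to cancel accumulated float drift
            for j in range(P):
                for i in range(pop_start[j], pop_end[j]):
                    s = y[i] - beta0
                    for k in range(K):
                        s -= Z[i, k] * ujk[j, k]
                    e[i] = s

    return (
        out_beta0,
        out_u,
        out_ujk,
        out_sig2,
        out_gamma,
        out_m,
        out_d,
        out_S2,
        out_sige,
    )
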