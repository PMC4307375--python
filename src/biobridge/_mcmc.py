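"""Numba-compiled Metropolis-within-Gibbs kernel.

One compiled function runs a whole chain over the state
``(beta0, beta, z_1..z_N)`` where ``z_i = logit(phi_B_i)``.  Proposals are
Gaussian random walks; per-parameter step sizes adapt toward a 0.44
acceptance rate during burn-in only, so the kept draws come from a fixed
transition kernel.

The kernel is shared by the user-facing fit (long chains) and the
simulation engine (thousands of short fits), which is why it is compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12
_CLIP = 1e-10  # sampler-internal clamp for proportions entering the link


@njit(cache=True, inline="always")
def _g(p, link_id):
    if link_id == 0:
        return p / (1.0 - p)
    elif link_id == 1:
        return np.log(p / (1.0 - p))
    else:
        return np.log(-np.log(1.0 - p))


@njit(cache=True, inline="always")
def _g_inv(y, link_id):
    # returns -1.0 to flag an undefined inverse (odds link, y <= 0)
    if link_id == 0:
        if y <= 0.0:
            return -1.0
        return y / (1.0 + y)
    elif link_id == 1:
        if y > 0.0:
            return 1.0 / (1.0 + np.exp(-y))
        ey = np.exp(y)
        return ey / (1.0 + ey)
    else:
        return 1.0 - np.exp(-np.exp(y))


@njit(cache=True, inline="always")
def _x_loglik(phi_b, beta0, beta, link_id, x_t, x_n):
    """Binomial log-likelihood of the endpoint counts given phi_B."""
    p = phi_b
    if p < _CLIP:
        p = _CLIP
    elif p > 1.0 - _CLIP:
        p = 1.0 - _CLIP
    eta = beta0 + beta * _g(p, link_id)
    px = _g_inv(eta, link_id)
    if px < 0.0:
        return -np.inf
    if px < _EPS:
        px = _EPS
    elif px > 1.0 - _EPS:
        px = 1.0 - _EPS
    return x_t * np.log(px) + (x_n - x_t) * np.log(1.0 - px)


@njit(cache=True, inline="always")
def _z_logpost(z, b_t, b_n, a_b, b_b):
    """Biomarker likelihood + Beta prior + logit-scale Jacobian, up to const.

    With phi = expit(z), prior Beta(a,b) and Jacobian phi*(1-phi) the
    exponents collapse to (a + b_t)*log(phi) + (b + b_n - b_t)*log(1-phi).
    """
    if z > 0.0:
        log_phi = -np.log1p(np.exp(-z))
        log_1mphi = -z + log_phi
    else:
        log_1mphi = -np.log1p(np.exp(z))
        log_phi = z + log_1mphi
    return (a_b + b_t) * log_phi + (b_b + b_n - b_t) * log_1mphi


@njit(cache=True)
def run_chain(
    b_t,
    b_n,
    x_t,
    x_n,
    link_id,
    beta0_sd,
    beta_lo,
    beta_hi,
    a_b,
    b_b,
    n_burn,
    n_iter,
    thin,
    seed,
    beta0_init,
    beta_init,
    z_init,
):
    """Run one adaptive Metropolis-within-Gibbs chain.

    Returns ``(beta0_draws, beta_draws, phi_b_draws)`` with
    ``n_iter // thin`` kept draws each.
    """
    np.random.seed(seed)
    n = b_t.shape[0]
    beta_fixed = beta_hi <= beta_lo

    beta0 = beta0_init
    beta = beta_init
    if beta_fixed:
        beta = beta_lo
    elif beta < beta_lo or beta > beta_hi:
        beta = 0.5 * (beta_lo + beta_hi)
    z = z_init.copy()
    phi = np.empty(n)
    for i in range(n):
        phi[i] = 1.0 / (1.0 + np.exp(-z[i]))

    x_ll = np.empty(n)
    z_lp = np.empty(n)
    for i in range(n):
        x_ll[i] = _x_loglik(phi[i], beta0, beta, link_id, x_t[i], x_n[i])
        z_lp[i] = _z_logpost(z[i], b_t[i], b_n[i], a_b, b_b)

    # if the initial state is unsupported (odds link), fall back to a state
    # guaranteed valid: beta0 slightly positive, beta at the safe side
    if link_id == 0:
        total = 0.0
        for i in range(n):
            total += x_ll[i]
        if not np.isfinite(total):
            beta0 = 1.0
            beta = 0.0 if not beta_fixed else beta
            if not beta_fixed and (beta < beta_lo or beta > beta_hi):
                beta = beta_lo if beta_lo > 0.0 else beta_hi
            for i in range(n):
                x_ll[i] = _x_loglik(phi[i], beta0, beta, link_id, x_t[i], x_n[i])

    s_beta0 = 0.5
    s_beta = 0.5
    s_z = np.full(n, 0.8)
    acc_beta0 = 0
    acc_beta = 0
    acc_z = np.zeros(n, dtype=np.int64)
    adapt_every = 50

    n_keep = n_iter // thin
    beta0_draws = np.empty(n_keep)
    beta_draws = np.empty(n_keep)
    phi_draws = np.empty((n_keep, n))
    kept = 0

    for t in range(n_burn + n_iter):
        # --- intercept update (affects every trial's endpoint term)
        prop0 = beta0 + s_beta0 * np.random.normal()
        new_ll = np.empty(n)
        delta = (beta0 * beta0 - prop0 * prop0) / (2.0 * beta0_sd * beta0_sd)
        for i in range(n):
            new_ll[i] = _x_loglik(phi[i], prop0, beta, link_id, x_t[i], x_n[i])
            delta += new_ll[i] - x_ll[i]
        if delta >= 0.0 or np.log(np.random.random()) < delta:
            beta0 = prop0
            x_ll = new_ll
            acc_beta0 += 1

        # --- slope update
        if not beta_fixed:
            propb = beta + s_beta * np.random.normal()
            if beta_lo <= propb <= beta_hi:
                new_ll = np.empty(n)
                delta = 0.0
                for i in range(n):
                    new_ll[i] = _x_loglik(
                        phi[i], beta0, propb, link_id, x_t[i], x_n[i]
                    )
                    delta += new_ll[i] - x_ll[i]
                if delta >= 0.0 or np.log(np.random.random()) < delta:
                    beta = propb
                    x_ll = new_ll
                    acc_beta += 1

        # --- per-trial biomarker shares
        for i in range(n):
            propz = z[i] + s_z[i] * np.random.normal()
            prop_phi = 1.0 / (1.0 + np.exp(-propz))
            lp_new = _z_logpost(propz, b_t[i], b_n[i], a_b, b_b)
            ll_new = _x_loglik(prop_phi, beta0, beta, link_id, x_t[i], x_n[i])
            delta = (lp_new + ll_new) - (z_lp[i] + x_ll[i])
            if delta >= 0.0 or np.log(np.random.random()) < delta:
                z[i] = propz
                phi[i] = prop_phi
                z_lp[i] = lp_new
                x_ll[i] = ll_new
                acc_z[i] += 1

        # --- step-size adaptation, burn-in only
        if t < n_burn and (t + 1) % adapt_every == 0:
            rate0 = acc_beta0 / adapt_every
            s_beta0 *= np.exp(0.6 * (rate0 - 0.44))
            acc_beta0 = 0
            if not beta_fixed:
                rateb = acc_beta / adapt_every
                s_beta *= np.exp(0.6 * (rateb - 0.44))
                acc_beta = 0
            for i in range(n):
                ratez = acc_z[i] / adapt_every
                s_z[i] *= np.exp(0.6 * (ratez - 0.44))
                acc_z[i] = 0

        if t >= n_burn and (t - n_burn) % thin == thin - 1:
            beta0_draws[kept] = beta0
            beta_draws[kept] = beta
            for i in range(n):
                phi_draws[kept, i] = phi[i]
            kept += 1

    return beta0_draws, beta_draws, phi_draws
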