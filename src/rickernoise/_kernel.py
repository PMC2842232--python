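"""Numba kernel for the adaptive random-walk Metropolis sampler.

All model variants share one log-target evaluator and one block-scan sampler.
Parameters live on an unconstrained scale (logs of positive quantities), with
the Jacobian terms included in the target, so every stored draw satisfies the
positivity constraints by construction.

Model codes:
    0  conjugate normal-mean toy (known likelihood SD, normal prior)
    1  M1  growth-rate noise, static K ~ InvGamma
    2  M2  hierarchical log-normal K_t
    3  M3  hierarchical, both shocks
    4  M2  literal iid InvGamma prior on each K_t
    5  M3  literal iid InvGamma prior on each K_t

Latent shocks are stored non-centered: z carries standardized shocks
``u_t ~ N(0, 1)`` and the likelihood uses ``eps_t = sigma_r u_t`` (and
``eta_t = sigma_k u_t``). This removes the funnel between the shock paths
and their scale parameters that cripples centered random-walk updates.

Prior vector layout (pv):
    [0] r_loc   [1] r_scale    (normal truncated to (0, inf), on r)
    [2] k_loc   [3] k_scale    (normal, on k = log K)
    [4] K_shape [5] K_scale    (inverse-gamma, on K or K_t)
    [6] v_shape [7] v_scale    (inverse-gamma, on each variance)
    [8] toy_lik_sd  [9] toy_prior_mean  [10] toy_prior_sd
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)
_INV_SQRT2 = 0.7071067811865476

TOY, M1, M2H, M3H, M2IID, M3IID = 0, 1, 2, 3, 4, 5


@njit(cache=True, error_model="numpy")
def _ndtr(x):
    """Standard normal CDF via erfc (numerically fine on (-8, inf))."""
    return 0.5 * math.erfc(-x * _INV_SQRT2)


@njit(cache=True, error_model="numpy")
def _invgamma_logpdf(x, shape, scale):
    return (
        shape * math.log(scale)
        - math.lgamma(shape)
        - (shape + 1.0) * math.log(x)
        - scale / x
    )


@njit(cache=True, error_model="numpy")
def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * LOG2PI


@njit(cache=True, error_model="numpy")
def log_target(z, y, model, pv, lik_scale):
    """Unnormalized log posterior on the unconstrained scale (-inf off support)."""
    T = y.shape[0]
    L = T - 1

    if model == TOY:
        m = z[0]
        lp = _norm_logpdf(m, pv[9], pv[10])
        s = pv[8]
        for t in range(T):
            lp += lik_scale * _norm_logpdf(y[t], m, s)
        return lp

    zr = z[0]
    if zr > 50.0:
        return -np.inf
    r = math.exp(zr)
    # truncated-normal prior on r, plus Jacobian of the log transform
    lp = _norm_logpdf(r, pv[0], pv[1]) - math.log(_ndtr(pv[0] / pv[1])) + zr

    s2r = 1.0
    s2k = 1.0
    if model == M1:
        zK = z[1]
        K = math.exp(zK)
        lp += _invgamma_logpdf(K, pv[4], pv[5]) + zK
        s2r = math.exp(z[2])
        lp += _invgamma_logpdf(s2r, pv[6], pv[7]) + z[2]
        s2o = math.exp(z[3])
        lp += _invgamma_logpdf(s2o, pv[6], pv[7]) + z[3]
        for j in range(L):
            lp += _norm_logpdf(z[4 + j], 0.0, 1.0)
    elif model == M2H:
        k = z[1]
        lp += _norm_logpdf(k, pv[2], pv[3])
        s2k = math.exp(z[2])
        lp += _invgamma_logpdf(s2k, pv[6], pv[7]) + z[2]
        s2o = math.exp(z[3])
        lp += _invgamma_logpdf(s2o, pv[6], pv[7]) + z[3]
        for j in range(L):
            lp += _norm_logpdf(z[4 + j], 0.0, 1.0)
    elif model == M3H:
        k = z[1]
        lp += _norm_logpdf(k, pv[2], pv[3])
        s2r = math.exp(z[2])
        lp += _invgamma_logpdf(s2r, pv[6], pv[7]) + z[2]
        s2k = math.exp(z[3])
        lp += _invgamma_logpdf(s2k, pv[6], pv[7]) + z[3]
        s2o = math.exp(z[4])
        lp += _invgamma_logpdf(s2o, pv[6], pv[7]) + z[4]
        for j in range(L):
            lp += _norm_logpdf(z[5 + j], 0.0, 1.0)
            lp += _norm_logpdf(z[5 + L + j], 0.0, 1.0)
    elif model == M2IID:
        s2o = math.exp(z[1])
        lp += _invgamma_logpdf(s2o, pv[6], pv[7]) + z[1]
        for j in range(L):
            zk = z[2 + j]
            if zk > 50.0:
                return -np.inf
            lp += _invgamma_logpdf(math.exp(zk), pv[4], pv[5]) + zk
    else:  # M3IID
        s2r = math.exp(z[1])
        lp += _invgamma_logpdf(s2r, pv[6], pv[7]) + z[1]
        s2o = math.exp(z[2])
        lp += _invgamma_logpdf(s2o, pv[6], pv[7]) + z[2]
        for j in range(L):
            lp += _norm_logpdf(z[3 + j], 0.0, 1.0)
            zk = z[3 + L + j]
            if zk > 50.0:
                return -np.inf
            lp += _invgamma_logpdf(math.exp(zk), pv[4], pv[5]) + zk

    if not math.isfinite(lp):
        return -np.inf

    if s2o <= 0.0 or s2r < 0.0 or s2k < 0.0:
        return -np.inf
    so = math.sqrt(s2o)
    sr = math.sqrt(s2r)
    sk = math.sqrt(s2k)
    for t in range(1, T):
        if model == M1:
            Kt = math.exp(z[1])
            e = sr * z[4 + (t - 1)]
        elif model == M2H:
            Kt = math.exp(z[1] + sk * z[4 + (t - 1)])
            e = 0.0
        elif model == M3H:
            Kt = math.exp(z[1] + sk * z[5 + L + (t - 1)])
            e = sr * z[5 + (t - 1)]
        elif model == M2IID:
            Kt = math.exp(z[2 + (t - 1)])
            e = 0.0
        else:
            Kt = math.exp(z[3 + L + (t - 1)])
            e = sr * z[3 + (t - 1)]
        if Kt <= 0.0 or not math.isfinite(Kt):
            return -np.inf
        g = r * (1.0 - y[t - 1] / Kt) + e
        if g > 700.0 or not math.isfinite(g):
            return -np.inf
        mu = y[t - 1] * math.exp(g)
        zz = (y[t] - mu) / so
        lp += lik_scale * (
            -0.5 * zz * zz - math.log(so) - 0.5 * LOG2PI - math.log(_ndtr(mu / so))
        )

    if not math.isfinite(lp):
        return -np.inf
    return lp


@njit(cache=True, error_model="numpy")
def run_chain(
    y,
    model,
    pv,
    lik_scale,
    z0,
    block_starts,
    block_sizes,
    block_targets,
    block_modes,
    step_init,
    n_scalar,
    n_burn,
    n_iter,
    thin,
    seed,
):
    """One chain of adaptive RWM within a fixed block scan.

    Per-block step sizes adapt by Robbins-Monro during burn-in only (frozen
    afterwards, preserving detailed balance). Blocks with mode 1 propose one
    shared N(0, step) increment for the whole coordinate range (a field
    shift): coordinated moves of a latent path against r or k are the slowest
    posterior direction and per-coordinate proposals cannot make them. The first ``n_scalar`` entries
    of z additionally get a joint random-walk update whose proposal
    covariance is learned from the burn-in history (Haario-style adaptive
    Metropolis, likewise frozen at the end of burn-in): the scalar
    parameters of these models sit on strong posterior ridges (r against K)
    that single-site proposals traverse slowly. Returns
    (draws, acceptance_rates); the last acceptance entry is the joint block.
    """
    np.random.seed(seed)
    dim = z0.shape[0]
    T = y.shape[0]
    L = T - 1
    n_blocks = block_starts.shape[0]
    z = z0.copy()
    lp = log_target(z, y, model, pv, lik_scale)
    ls = np.log(step_init).copy()

    # adaptive step for the r <-> K_t ridge move of the iid-prior models
    ls_ridge = math.log(0.3)

    # adaptive-covariance state for the joint scalar block
    ls_joint = math.log(0.3)
    mean_s = np.zeros(n_scalar)
    cov_s = np.eye(n_scalar)
    chol = np.eye(n_scalar) * 0.1
    n_hist = 0.0

    n_keep = n_iter // thin
    draws = np.empty((n_keep, dim))
    acc_ct = np.zeros(n_blocks + 1)
    prop_ct = np.zeros(n_blocks + 1)
    kept = 0

    total = n_burn + n_iter
    prop = np.empty(dim)
    for it in range(total):
        for b in range(n_blocks):
            s = block_starts[b]
            w = block_sizes[b]
            step = math.exp(ls[b])
            for j in range(dim):
                prop[j] = z[j]
            if block_modes[b] == 1:
                shift = step * np.random.normal()
                for j in range(s, s + w):
                    prop[j] = z[j] + shift
            else:
                for j in range(s, s + w):
                    prop[j] = z[j] + step * np.random.normal()
            lp_prop = log_target(prop, y, model, pv, lik_scale)
            acc = 0.0
            if lp_prop - lp > math.log(np.random.random() + 1e-300):
                for j in range(dim):
                    z[j] = prop[j]
                lp = lp_prop
                acc = 1.0
            if it < n_burn:
                gamma = 2.0 / (1.0 + it) ** 0.6
                ls[b] += gamma * (acc - block_targets[b])
                if ls[b] < -15.0:
                    ls[b] = -15.0
                elif ls[b] > 5.0:
                    ls[b] = 5.0
            else:
                prop_ct[b] += 1.0
                acc_ct[b] += acc

        # joint scalar update with learned covariance
        step = math.exp(ls_joint)
        for j in range(dim):
            prop[j] = z[j]
        for i in range(n_scalar):
            u = 0.0
            for j in range(i + 1):
                u += chol[i, j] * np.random.normal()
            prop[i] = z[i] + step * u
        lp_prop = log_target(prop, y, model, pv, lik_scale)
        acc = 0.0
        if lp_prop - lp > math.log(np.random.random() + 1e-300):
            for j in range(dim):
                z[j] = prop[j]
            lp = lp_prop
            acc = 1.0
        if it < n_burn:
            gamma = 2.0 / (1.0 + it) ** 0.6
            ls_joint += gamma * (acc - 0.25)
            if ls_joint < -15.0:
                ls_joint = -15.0
            elif ls_joint > 5.0:
                ls_joint = 5.0
            # online mean/covariance of the scalar history
            n_hist += 1.0
            w = 1.0 / n_hist
            for i in range(n_scalar):
                d_i = z[i] - mean_s[i]
                mean_s[i] += w * d_i
                for j in range(i + 1):
                    d_j = z[j] - mean_s[j]
                    upd = w * (d_i * d_j - cov_s[i, j]) if n_hist > 1.0 else 0.0
                    cov_s[i, j] += upd
                    cov_s[j, i] = cov_s[i, j]
            if n_hist >= 50.0 and it % 50 == 0:
                reg = cov_s.copy()
                for i in range(n_scalar):
                    reg[i, i] += 1e-8
                chol = np.linalg.cholesky(reg)
        else:
            prop_ct[n_blocks] += 1.0
            acc_ct[n_blocks] += acc

        # ridge move for the iid-K_t models: the likelihood depends on
        # (r, K_t) only through g_t = r (1 - y_{t-1}/K_t), so multiply r by
        # exp(delta) and remap every K_t to keep g_t fixed; only the priors
        # decide acceptance. Deterministic-map MH with log-Jacobian
        # sum log((r - g_t)/(r' - g_t)) on the log-K coordinates.
        if model == M2IID or model == M3IID:
            base = 2 if model == M2IID else 3 + L
            delta = math.exp(ls_ridge) * np.random.normal()
            r_cur = math.exp(z[0])
            r_new = r_cur * math.exp(delta)
            for j in range(dim):
                prop[j] = z[j]
            prop[0] = z[0] + delta
            log_jac = 0.0
            ok = True
            for t in range(1, T):
                K = math.exp(z[base + t - 1])
                g = r_cur * (1.0 - y[t - 1] / K)
                denom = r_new - g
                if denom <= 0.0:
                    ok = False
                    break
                prop[base + t - 1] = math.log(r_new * y[t - 1] / denom)
                log_jac += math.log((r_cur - g) / denom)
            acc = 0.0
            if ok:
                lp_prop = log_target(prop, y, model, pv, lik_scale)
                if lp_prop + log_jac - lp > math.log(np.random.random() + 1e-300):
                    for j in range(dim):
                        z[j] = prop[j]
                    lp = lp_prop
                    acc = 1.0
            if it < n_burn:
                gamma = 2.0 / (1.0 + it) ** 0.6
                ls_ridge += gamma * (acc - 0.25)
                if ls_ridge < -15.0:
                    ls_ridge = -15.0
                elif ls_ridge > 5.0:
                    ls_ridge = 5.0

        if it >= n_burn and (it - n_burn) % thin == thin - 1:
            for j in range(dim):
                draws[kept, j] = z[j]
            kept += 1

    rates = np.empty(n_blocks + 1)
    for b in range(n_blocks + 1):
        rates[b] = acc_ct[b] / prop_ct[b] if prop_ct[b] > 0 else np.nan
    return draws, rates
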