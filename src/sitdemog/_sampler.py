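"""Slice-within-Gibbs sampler for the mixed-effect binomial logit model.

Model, in non-centered form:

    y_i ~ Binomial(m_i, p_i),  logit(p_i) = beta_{t(i)} + sigma * z_i
    beta_t ~ Normal(0, sd_beta^2)   (flat when sd_beta is infinite)
    z_i ~ Normal(0, 1),  sigma ~ HalfNormal(1), sampled as eta = log(sigma)

Each coordinate is updated by univariate slice sampling (stepping-out plus
shrinkage), which is tuning-free and, with a fixed seed, fully
deterministic — a requirement for byte-identical pipeline reports.  The
kernels are plain nopython-compatible NumPy so they JIT under numba when it
is importable and still run (slowly) without it.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["run_chain", "HAVE_NUMBA"]

_W = 1.0          # initial slice width (logit scale)
_MAX_STEPS = 30   # stepping-out cap


def _logpost(theta, y, m, tidx, n_beta, beta_prec, sample_re):
    n = y.shape[0]
    lp = 0.0
    for t in range(n_beta):
        lp -= 0.5 * beta_prec * theta[t] * theta[t]
    sigma = 0.0
    if sample_re:
        eta = theta[n_beta + n]
        sigma = math.exp(eta)
        lp += -0.5 * sigma * sigma + eta  # HalfNormal(1) + log-Jacobian
        for i in range(n):
            z = theta[n_beta + i]
            lp -= 0.5 * z * z
    for i in range(n):
        lin = theta[tidx[i]]
        if sample_re:
            lin += sigma * theta[n_beta + i]
        # softplus(lin) computed stably
        if lin > 30.0:
            sp = lin
        elif lin < -30.0:
            sp = 0.0
        else:
            sp = math.log1p(math.exp(lin))
        lp += y[i] * lin - m[i] * sp
    return lp


def _slice_update(theta, j, y, m, tidx, n_beta, beta_prec, sample_re, lp0):
    """One slice-sampling move of coordinate j; returns the new log-posterior."""
    x0 = theta[j]
    log_level = lp0 + math.log(np.random.random())
    left = x0 - _W * np.random.random()
    right = left + _W
    j_steps = int(np.random.random() * _MAX_STEPS)
    k_steps = _MAX_STEPS - 1 - j_steps
    theta[j] = left
    while j_steps > 0 and _logpost(theta, y, m, tidx, n_beta, beta_prec, sample_re) > log_level:
        left -= _W
        theta[j] = left
        j_steps -= 1
    theta[j] = right
    while k_steps > 0 and _logpost(theta, y, m, tidx, n_beta, beta_prec, sample_re) > log_level:
        right += _W
        theta[j] = right
        k_steps -= 1
    while True:
        x1 = left + np.random.random() * (right - left)
        theta[j] = x1
        lp1 = _logpost(theta, y, m, tidx, n_beta, beta_prec, sample_re)
        if lp1 >= log_level:
            return lp1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _ancillary_moves(theta, y, m, tidx, n_beta, beta_prec):
    """Likelihood-invariant Metropolis moves along the beta/z and sigma/z
    ridges of the non-centered parameterization.

    Translation (per treatment): beta_t += d, z_i -= d/sigma for rows in t,
    leaves every linear predictor unchanged (Jacobian 1).  Scale: eta += e,
    z *= exp(-e), leaves sigma*z unchanged (log-Jacobian -n*e).  Both are
    accepted on the prior ratio only, which breaks the strong posterior
    anticorrelation that slows single-site updates.
    """
    n = y.shape[0]
    eta = theta[n_beta + n]
    sigma = math.exp(eta)
    for t in range(n_beta):
        d = 0.25 * np.random.standard_normal()
        b_old = theta[t]
        b_new = b_old + d
        log_acc = -0.5 * beta_prec * (b_new * b_new - b_old * b_old)
        for i in range(n):
            if tidx[i] == t:
                z_old = theta[n_beta + i]
                z_new = z_old - d / sigma
                log_acc += -0.5 * (z_new * z_new - z_old * z_old)
        if math.log(np.random.random()) < log_acc:
            theta[t] = b_new
            for i in range(n):
                if tidx[i] == t:
                    theta[n_beta + i] -= d / sigma
    e = 0.3 * np.random.standard_normal()
    eta_new = eta + e
    sigma_new = math.exp(eta_new)
    log_acc = (-0.5 * sigma_new * sigma_new + eta_new) \
        - (-0.5 * sigma * sigma + eta) - n * e
    scale = math.exp(-e)
    for i in range(n):
        z_old = theta[n_beta + i]
        z_new = z_old * scale
        log_acc += -0.5 * (z_new * z_new - z_old * z_old)
    if math.log(np.random.random()) < log_acc:
        theta[n_beta + n] = eta_new
        for i in range(n):
            theta[n_beta + i] *= scale


def _run_chain_impl(y, m, tidx, n_beta, theta0, beta_prec, sample_re,
                    n_warmup, n_keep, seed):
    np.random.seed(seed)
    dim = theta0.shape[0]
    theta = theta0.copy()
    out = np.empty((n_keep, dim))
    lp = _logpost(theta, y, m, tidx, n_beta, beta_prec, sample_re)
    for it in range(n_warmup + n_keep):
        for j in range(dim):
            lp = _slice_update(theta, j, y, m, tidx, n_beta, beta_prec,
                               sample_re, lp)
        if sample_re:
            _ancillary_moves(theta, y, m, tidx, n_beta, beta_prec)
            lp = _logpost(theta, y, m, tidx, n_beta, beta_prec, sample_re)
        if it >= n_warmup:
            out[it - n_warmup] = theta
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _logpost = numba.njit(cache=True)(_logpost)
    _slice_update = numba.njit(cache=True)(_slice_update)
    _ancillary_moves = numba.njit(cache=True)(_ancillary_moves)
    _run_chain_impl = numba.njit(cache=True)(_run_chain_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def run_chain(y: np.ndarray, m: np.ndarray, tidx: np.ndarray, n_beta: int,
              theta0: np.ndarray, *, beta_prec: float, sample_re: bool,
              n_warmup: int, n_keep: int, seed: int) -> np.ndarray:
    """Run one chain; rows of the result are kept parameter vectors.

    Layout: ``theta = [beta_0..beta_{T-1}, z_0..z_{n-1}, log_sigma]`` when
    ``sample_re``, else just the betas.
    """
    return _run_chain_impl(
        np.asarray(y, dtype=np.float64), np.asarray(m, dtype=np.float64),
        np.asarray(tidx, dtype=np.int64), n_beta,
        np.asarray(theta0, dtype=np.float64), float(beta_prec),
        bool(sample_re), int(n_warmup), int(n_keep), int(seed) % (2**31 - 1))
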