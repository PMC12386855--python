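"""Split-R-hat and effective-sample-size diagnostics for MCMC output.

Self-contained implementations of the split potential-scale-reduction
statistic and the variogram/initial-positive-sequence effective sample size,
so the sampler gate does not depend on optional packages.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_rhat", "ess", "summarize_chains"]


def _split(chains: np.ndarray) -> np.ndarray:
    """(c, n) -> (2c, n//2); drops one iteration from odd-length chains."""
    c, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)


def split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction factor for one scalar parameter."""
    x = _split(np.asarray(chains, dtype=float))
    m, n = x.shape
    if n < 2:
        return np.nan
    chain_means = x.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = x.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess(chains: np.ndarray) -> float:
    """Effective sample size using the variogram estimator with Geyer's
    initial monotone positive sequence."""
    x = _split(np.asarray(chains, dtype=float))
    m, n = x.shape
    if n < 4:
        return float(m * n)
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    if var_plus == 0:
        return float(m * n)
    max_lag = n - 1
    rho = np.empty(max_lag)
    for t in range(1, max_lag + 1):
        vt = np.mean((x[:, t:] - x[:, :-t]) ** 2)
        rho[t - 1] = 1.0 - vt / (2.0 * var_plus)
    # pair sums; truncate at first negative pair, enforce monotone decrease
    tau = 1.0
    prev_pair = np.inf
    t = 0
    while t + 1 < max_lag:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


def summarize_chains(chains: np.ndarray, names: list[str]) -> dict:
    """Per-parameter R-hat/ESS for a (chains, iterations, params) array."""
    c, n, p = chains.shape
    rhats = {names[j]: split_rhat(chains[:, :, j]) for j in range(p)}
    esss = {names[j]: ess(chains[:, :, j]) for j in range(p)}
    finite_r = [v for v in rhats.values() if np.isfinite(v)]
    return {
        "rhat": rhats,
        "ess": esss,
        "max_rhat": max(finite_r) if finite_r else np.nan,
        "min_ess": min(esss.values()) if esss else np.nan,
    }
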