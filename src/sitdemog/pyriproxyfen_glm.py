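"""Zero-augmented gamma regression for ovitrap water concentrations.

Two-part hurdle model: a logistic part for the probability of a structural
zero and, conditional on a positive measurement, a gamma distribution with a
logarithmic link between its mean and the linear predictor and a shape
parameter shared across observations.  The joint likelihood factorizes, so
the parts are fit separately by maximum likelihood with deterministic
moment-based starts:

    L = prod_{y_i = 0} pi_i  *  prod_{y_i > 0} (1 - pi_i) Gamma(y_i; k, mu_i)

Likelihood-ratio tests compare nested fits on the same observations; Wald
tests compare single coefficients with reference values using standard
errors from the observed information matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ZAGFit",
    "TestResult",
    "fit_zag",
    "lrt",
    "wald",
    "design_from_frame",
    "flag_outliers",
]

_LL_TOL = 1e-8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class ZAGFit:
    zero_coefs: np.ndarray          # logit coefficients, P(structural zero)
    pos_coefs: np.ndarray           # log-link gamma mean coefficients
    shape: float                    # shared gamma shape (nan for degenerate fits)
    log_likelihood: float
    n_obs: int
    design_labels: list[str]        # covariate labels (intercept excluded)
    param_names: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None   # observed-information covariance
    degenerate: bool = False        # all-zero response: zero part only

    @property
    def n_params(self) -> int:
        return len(self.zero_coefs) + len(self.pos_coefs) + (0 if self.degenerate else 1)

    def coef(self, name: str) -> float:
        return dict(zip(self.param_names, self._params()))[name]

    def se(self, name: str) -> float:
        if self.cov is None:
            raise ValueError("no covariance available (degenerate fit?)")
        i = self.param_names.index(name)
        v = self.cov[i, i]
        if not np.isfinite(v) or v <= 0:
            raise ValueError(
                f"non-positive variance for {name!r}: singular information "
                "matrix (possible separation or collinearity)")
        return float(np.sqrt(v))

    def _params(self) -> np.ndarray:
        if self.degenerate:
            return np.asarray(self.zero_coefs)
        return np.concatenate([self.zero_coefs, self.pos_coefs,
                               [np.log(self.shape)]])


def design_from_frame(frame: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Minimal design-matrix builder: numeric columns as-is, booleans as 0/1,
    strings dummy-coded dropping the first level.  No intercept column (the
    fitters add one)."""
    cols, labels = [], []
    for term in terms:
        if term not in frame.columns:
            raise KeyError(f"unknown covariate {term!r}")
        s = frame[term]
        if s.dtype == bool:
            cols.append(s.to_numpy(dtype=float))
            labels.append(term)
        elif np.issubdtype(s.dtype, np.number):
            cols.append(s.to_numpy(dtype=float))
            labels.append(term)
        else:
            values = sorted(s.astype(str).unique())
            for v in values[1:]:
                cols.append((s.astype(str) == v).to_numpy(dtype=float))
                labels.append(f"{term}[{v}]")
    x = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return x, labels


def _add_intercept(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(x.shape[0]), x])


def _logistic_nll(beta: np.ndarray, x: np.ndarray, w: np.ndarray) -> float:
    eta = x @ beta
    return float(np.sum(np.logaddexp(0.0, eta)) - w @ eta)


def _logistic_grad(beta: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    pi = special.expit(x @ beta)
    return x.T @ (pi - w)


def _fit_logistic(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """MLE of P(w=1) on a design with intercept; deterministic multi-start."""
    p0 = np.clip(w.mean(), 1e-3, 1 - 1e-3)
    starts = [np.zeros(x.shape[1]), np.r_[special.logit(p0), np.zeros(x.shape[1] - 1)]]
    best = None
    for s in starts:
        res = optimize.minimize(_logistic_nll, s, args=(x, w), jac=_logistic_grad,
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun - _LL_TOL:
            best = res
    return best.x


def _fit_gamma_glm(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Gamma GLM with log link (Fisher scoring for the mean, then the exact
    shape MLE by root finding; the mean score does not involve the shape)."""
    n, p = x.shape
    beta = np.zeros(p)
    beta[0] = np.log(y.mean())
    for _ in range(200):
        mu = np.exp(np.clip(x @ beta, -500, 500))
        score = x.T @ (y / mu - 1.0)
        step = np.linalg.solve(x.T @ x, score)
        beta_new = beta + step
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(x @ beta)
    s = float(np.sum(np.log(y / mu) - y / mu))  # <= -n, equality iff saturated

    def dll_dk(k: float) -> float:
        return n * (np.log(k) + 1.0 - special.digamma(k)) + s

    if s >= -n + 1e-12:  # numerically saturated fit: shape unbounded
        return beta, np.inf
    shape = optimize.brentq(dll_dk, 1e-10, 1e10, xtol=1e-12, rtol=1e-14)
    return beta, shape


def _gamma_ll(y: np.ndarray, mu: np.ndarray, k: float) -> float:
    return float(np.sum(k * np.log(k / mu) + (k - 1.0) * np.log(y)
                        - k * y / mu - special.gammaln(k)))


def _numeric_hessian(f, x0: np.ndarray, h: float = 1e-5) -> np.ndarray:
    p = x0.size
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4.0 * h * h)
    return hess


def fit_zag(y, x: np.ndarray | None = None,
            design_labels: list[str] | None = None) -> ZAGFit:
    """Maximum-likelihood fit of the zero-augmented gamma model.

    ``x`` holds the covariate columns (no intercept; one is always added to
    both parts).  With an all-zero response a degenerate zero-part-only fit
    is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be non-negative")
    n = y.size
    if x is None:
        x = np.empty((n, 0))
    x = np.asarray(x, dtype=float)
    if x.shape[0] != n:
        raise ValueError("covariate rows must match response length")
    labels = list(design_labels) if design_labels is not None \
        else [f"x{j}" for j in range(x.shape[1])]
    if n < x.shape[1] + 2:
        raise ValueError("need n >= p + 2 observations")

    xd = _add_intercept(x)
    is_zero = (y == 0).astype(float)
    zero_names = ["zero:intercept"] + [f"zero:{l}" for l in labels]
    pos_names = ["pos:intercept"] + [f"pos:{l}" for l in labels]

    if is_zero.all():
        warnings.warn("all-zero response: fitting the zero part only", UserWarning,
                      stacklevel=2)
        zb = _fit_logistic(xd, is_zero)
        return ZAGFit(zero_coefs=zb, pos_coefs=np.empty(0), shape=float("nan"),
                      log_likelihood=-_logistic_nll(zb, xd, is_zero),
                      n_obs=n, design_labels=labels, param_names=zero_names,
                      degenerate=True)

    zero_beta = _fit_logistic(xd, is_zero)
    pos_mask = y > 0
    pos_beta, shape = _fit_gamma_glm(xd[pos_mask], y[pos_mask])
    mu = np.exp(xd[pos_mask] @ pos_beta)
    ll = -_logistic_nll(zero_beta, xd, is_zero) + _gamma_ll(y[pos_mask], mu, shape)

    names = zero_names + pos_names + ["log_shape"]
    xp, yp = xd[pos_mask], y[pos_mask]
    nz, npar = len(zero_beta), len(pos_beta)

    def joint_nll(params: np.ndarray) -> float:
        zb, pb, k = params[:nz], params[nz:nz + npar], np.exp(params[-1])
        mu_ = np.exp(np.clip(xp @ pb, -500, 500))
        return _logistic_nll(zb, xd, is_zero) - _gamma_ll(yp, mu_, k)

    cov = None
    if np.isfinite(shape):
        packed = np.concatenate([zero_beta, pos_beta, [np.log(shape)]])
        hess = _numeric_hessian(joint_nll, packed)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = None
    return ZAGFit(zero_coefs=zero_beta, pos_coefs=pos_beta, shape=float(shape),
                  log_likelihood=float(ll), n_obs=n, design_labels=labels,
                  param_names=names, cov=cov)


def lrt(nested: ZAGFit, full: ZAGFit) -> TestResult:
    """Likelihood-ratio chi-square test of ``full`` against ``nested``.

    The p-value is always computed from (statistic, df) via the chi-square
    upper tail — never transcribed from elsewhere.
    """
    if nested.n_obs != full.n_obs:
        raise ValueError("fits use different observation counts")
    if not set(nested.design_labels) <= set(full.design_labels):
        raise ValueError("models are not nested: "
                         f"{nested.design_labels} vs {full.design_labels}")
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError("nested model has more parameters than the full model")
    statistic = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return TestResult(statistic=statistic, p_value=p, df=df)


def wald(fit: ZAGFit, coefficient: str, reference_value: float = 0.0,
         *, direction: str | None = None) -> TestResult:
    """Wald t-test of one coefficient against a reference value.

    Two-sided by default; ``direction`` in {"greater", "less"} gives the
    one-sided tail.  Degrees of freedom: n_obs - n_params.
    """
    if coefficient not in fit.param_names:
        raise KeyError(f"unknown coefficient {coefficient!r}; "
                       f"available: {fit.param_names}")
    est = fit.coef(coefficient)
    se = fit.se(coefficient)
    t = (est - reference_value) / se
    df = max(fit.n_obs - fit.n_params, 1)
    if direction is None:
        p = 2.0 * float(stats.t.sf(abs(t), df))
    elif direction == "greater":
        p = float(stats.t.sf(t, df))
    elif direction == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise ValueError("direction must be None, 'greater' or 'less'")
    return TestResult(statistic=float(t), p_value=min(p, 1.0), df=None)


def flag_outliers(y, threshold: float = 3.5) -> np.ndarray:
    """Robust-distance outlier flags on the positive measurements (modified
    z-score on logs against the median/MAD).  Flags only — observations are
    never auto-removed."""
    y = np.asarray(y, dtype=float)
    flags = np.zeros(y.size, dtype=bool)
    pos = y > 0
    if pos.sum() < 3:
        return flags
    logs = np.log(y[pos])
    med = np.median(logs)
    mad = np.median(np.abs(logs - med))
    if mad == 0:
        return flags
    flags[pos] = 0.6745 * np.abs(logs - med) / mad > threshold
    return flags
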