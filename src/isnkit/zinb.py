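"""Zero-inflated negative binomial (ZINB) marginals for the copula model.

The ZINB law mixes a point mass at zero (probability ``pi``) with a negative
binomial of mean ``mu`` and dispersion ``theta`` (variance mu + mu^2/theta).
This module provides the distribution functions, quantile inversion used by
the synthetic generator, a maximum-likelihood regression of log-mean on
covariates (with a per-sample offset for sequencing depth), and the discrete
probability-integral transform that turns observed counts into latent normal
scores for the graphical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtri, logsumexp

_EPS = 1e-12


def _nb_p(mu: np.ndarray, theta: float) -> np.ndarray:
    """scipy's success probability for NB(mean=mu, dispersion=theta)."""
    return theta / (theta + np.maximum(mu, _EPS))


def zinb_cdf(x, mu, theta, pi):
    """F(x) = pi*1[x >= 0] + (1-pi) * F_NB(x); vectorized, x may be negative."""
    x = np.asarray(x, dtype=float)
    nb = stats.nbinom.cdf(x, theta, _nb_p(np.asarray(mu, dtype=float), theta))
    out = pi * (x >= 0) + (1.0 - pi) * nb
    return out


def zinb_ppf(u, mu, theta, pi):
    """Quantile of the zero-inflated CDF.

    Ties at zero follow the discrete-copula convention: every
    u <= pi + (1-pi) * F_NB(0) maps to zero.
    """
    u = np.asarray(u, dtype=float)
    if pi >= 1.0:
        return np.zeros_like(u)
    v = np.clip((u - pi) / (1.0 - pi), 0.0, 1.0 - _EPS)
    x = stats.nbinom.ppf(v, theta, _nb_p(np.asarray(mu, dtype=float), theta))
    return np.where(v <= 0.0, 0.0, x)  # u <= pi is the structural-zero branch


def zinb_logpmf(y, mu, theta, pi):
    y = np.asarray(y, dtype=float)
    lp_nb = stats.nbinom.logpmf(y, theta, _nb_p(mu, theta))
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi) if pi > 0 else -np.inf
        log1m = np.log1p(-pi) if pi < 1 else -np.inf
    out = log1m + lp_nb
    zero = y == 0
    if np.any(zero):
        stacked = np.stack([np.full(np.sum(zero), log_pi), out[zero]])
        out = out.copy()
        out[zero] = logsumexp(stacked, axis=0)
    return out


@dataclass
class ZinbTaxonFit:
    """MLE of a single taxon's ZINB regression.

    ``beta`` are coefficients on log-mean for the design matrix (first column
    is the intercept); ``mu`` below always refers to the intercept-level mean
    exp(beta0) at offset 0.
    """

    beta: np.ndarray
    theta: float
    pi: float
    loglik: float
    converged: bool
    fallback_nb: bool = False

    @property
    def mu(self) -> float:
        return float(np.exp(self.beta[0]))

    def mean(self, X: np.ndarray, offset: np.ndarray) -> np.ndarray:
        eta = offset + X @ self.beta
        return np.exp(np.clip(eta, -30.0, 30.0))


def _zinb_nll(params, y, X, offset, zero_inflated):
    p = X.shape[1]
    beta = params[:p]
    theta = np.exp(np.clip(params[p], -10.0, 10.0))
    pi = 1.0 / (1.0 + np.exp(-params[p + 1])) if zero_inflated else 0.0
    mu = np.exp(np.clip(offset + X @ beta, -30.0, 30.0))
    ll = zinb_logpmf(y, mu, theta, pi)
    if not np.all(np.isfinite(ll)):
        return 1e10
    return -float(np.sum(ll))


def fit_zinb_regression(
    y: np.ndarray,
    X: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    zero_inflated: bool = True,
) -> ZinbTaxonFit:
    """Maximum-likelihood ZINB regression with log link.

    Parameters
    ----------
    y : integer counts (n,)
    X : design matrix (n, p) WITHOUT an intercept column; the intercept is
        prepended here. ``None`` fits an intercept-only model.
    offset : per-sample offset on log mu (typically log sequencing depth,
        centred); ``None`` means zero.
    zero_inflated : if False, fit a plain NB (pi = 0).

    Falls back to a plain NB fit if the ZINB optimisation fails to converge;
    the returned fit records that with ``fallback_nb``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.empty((n, 0))
    X = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    ybar = max(np.mean(y), 0.1)
    zero_frac = np.mean(y == 0)
    p = X.shape[1]

    # moment start: excess zeros beyond a Poisson-ish baseline seed pi
    pi0 = min(max(zero_frac - np.exp(-ybar), 0.01), 0.9) if zero_inflated else 0.0
    beta0 = np.zeros(p)
    beta0[0] = np.log(ybar / max(1.0 - pi0, 0.1))
    v = np.var(y) if np.var(y) > ybar else ybar * 1.5
    theta0 = max(ybar**2 / max(v - ybar, 0.1), 0.1)
    x0 = np.concatenate([beta0, [np.log(theta0)], [np.log(pi0 / (1 - pi0)) if zero_inflated else 0.0]])

    res = optimize.minimize(
        _zinb_nll, x0, args=(y, X, offset, zero_inflated), method="L-BFGS-B",
        options={"maxiter": 500},
    )
    ok = bool(res.success) and np.isfinite(res.fun)
    if not ok and zero_inflated:
        # NB fallback (pi = 0): drop the inflation parameter
        nb = fit_zinb_regression(y, X[:, 1:], offset, zero_inflated=False)
        return ZinbTaxonFit(nb.beta, nb.theta, 0.0, nb.loglik, nb.converged, fallback_nb=True)
    beta = res.x[:p]
    theta = float(np.exp(np.clip(res.x[p], -10.0, 10.0)))
    pi = float(1.0 / (1.0 + np.exp(-res.x[p + 1]))) if zero_inflated else 0.0
    return ZinbTaxonFit(beta, theta, pi, -float(res.fun), ok)


def normal_scores(
    y: np.ndarray,
    mu: np.ndarray,
    theta: float,
    pi: float,
    method: str = "mid",
    rng: np.random.Generator | None = None,
    n_draws: int = 5,
) -> np.ndarray:
    """Latent normal scores from the fitted discrete CDF.

    ``mid`` uses the deterministic mid-probability v = (F(y-1) + F(y))/2;
    ``randomized`` draws v ~ U[F(y-1), F(y)] and averages the resulting
    z-scores over ``n_draws`` seeded draws. Both are standard treatments of
    ties in a discrete copula.
    """
    y = np.asarray(y, dtype=float)
    lo = zinb_cdf(y - 1, mu, theta, pi)
    hi = zinb_cdf(y, mu, theta, pi)
    if method == "mid":
        v = 0.5 * (lo + hi)
        return ndtri(np.clip(v, _EPS, 1.0 - _EPS))
    if method == "randomized":
        if rng is None:
            rng = np.random.default_rng(0)
        zs = np.zeros_like(y)
        for _ in range(n_draws):
            v = lo + rng.random(y.shape) * (hi - lo)
            zs += ndtri(np.clip(v, _EPS, 1.0 - _EPS))
        return zs / n_draws
    raise ValueError(f"unknown score method: {method!r}")
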