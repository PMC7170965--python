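"""Negative-binomial GLM with log link for per-peak count models.

The model for peak i, sample j is

    log mu_ij = beta0 + beta_ip * X_j^IP + beta_stim * X_j^STIM
                + beta_interaction * X_j^STIM:IP + log s_j

with X^IP indicating IP (vs input) libraries, X^STIM indicating the treated
condition, and s_j the sample's size factor entering as an offset.  Counts
are NB(mu, phi) with Var = mu + phi * mu^2; phi = 0 recovers Poisson.  The
reduced model drops the interaction; the difference in deviances at a shared
dispersion is referred to chi-squared with 1 df to test whether antibody
enrichment changes with the condition beyond any gene-expression change.

Fitting is iteratively reweighted least squares (IRLS), the canonical GLM
algorithm, written here so the deviance bookkeeping, offsets and fixed
dispersion match the test construction exactly; independent numerical
optimizers serve as oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

_EPS = 1e-10
_PHI_POISSON = 1e-9  # dispersions at or below this are treated as Poisson
LRT_CLIP_TOL = 1e-6


def nb_loglik(y, mu, phi) -> np.ndarray:
    """Elementwise NB log-pmf with Var = mu + phi*mu^2 (phi=0 -> Poisson).

    Broadcasts over any common shape.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _EPS)
    # below ~1e-9 the NB pmf is numerically indistinguishable from (and
    # analytically converges to) the Poisson limit; gammaln(y + 1/phi) would
    # lose precision there
    if np.isscalar(phi) or np.ndim(phi) == 0:
        if phi <= _PHI_POISSON:
            return y * np.log(mu) - mu - special.gammaln(y + 1.0)
        phi = float(phi)
        r = 1.0 / phi
        p = r / (r + mu)
        return (
            special.gammaln(y + r) - special.gammaln(r)
            - special.gammaln(y + 1.0) + r * np.log(p) + y * np.log1p(-p)
        )
    phi = np.asarray(phi, dtype=float)
    pois = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    r = 1.0 / np.maximum(phi, _PHI_POISSON)
    p = r / (r + mu)
    nb = (special.gammaln(y + r) - special.gammaln(r)
          - special.gammaln(y + 1.0) + r * np.log(p) + y * np.log1p(-p))
    return np.where(phi <= _PHI_POISSON, pois, nb)


def nb_deviance(y, mu, phi) -> float:
    """Total deviance 2*(loglik_saturated - loglik_model) at fixed phi."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, _EPS) / mu), 0.0)
    if phi <= _PHI_POISSON:
        unit = 2.0 * (ylogy - (y - mu))
    else:
        unit = 2.0 * (ylogy - (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu)))
    return float(np.sum(unit))


@dataclass
class GLMFit:
    beta: np.ndarray
    mu: np.ndarray
    deviance: float
    loglik: float
    converged: bool
    degenerate: bool
    n_iter: int


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    phi: float,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMFit:
    """Maximize the NB log-likelihood over beta by IRLS at fixed dispersion.

    Convergence: relative deviance change < ``tol``; the flag is False if not
    reached within ``max_iter``.  An all-zero row is returned degenerate (it
    carries no information about any coefficient).
    """
    y = np.asarray(y, dtype=float)
    if phi <= _PHI_POISSON:
        phi = 0.0
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    if np.all(y == 0):
        beta = np.full(p, np.nan)
        beta[0] = -np.inf
        return GLMFit(beta, np.zeros(n), 0.0, float(nb_loglik(y, _EPS, phi).sum()),
                      converged=True, degenerate=True, n_iter=0)

    mu = (y + np.mean(y)) / 2.0 + 0.1
    eta = np.log(mu)
    dev = nb_deviance(y, mu, phi)
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu / (1.0 + phi * mu)  # IRLS working weights for log link
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(np.maximum(w, _EPS))
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta_new = X @ beta_new + offset
        eta_new = np.clip(eta_new, -30.0, 30.0)
        mu_new = np.exp(eta_new)
        dev_new = nb_deviance(y, mu_new, phi)
        # step-halving if the deviance worsened (rare, extreme starts)
        step = 1.0
        while dev_new > dev + 1e-8 and step > 1e-4:
            step /= 2.0
            beta_try = beta + step * (beta_new - beta)
            eta_new = np.clip(X @ beta_try + offset, -30.0, 30.0)
            mu_new = np.exp(eta_new)
            dev_new = nb_deviance(y, mu_new, phi)
            beta_new = beta_try
        rel = abs(dev - dev_new) / (abs(dev) + 0.1)
        beta, eta, mu, dev = beta_new, eta_new, mu_new, dev_new
        if rel < tol:
            converged = True
            break
    ll = float(nb_loglik(y, mu, phi).sum())
    return GLMFit(beta, mu, dev, ll, converged=converged, degenerate=False, n_iter=it)


def lrt_interaction(full: GLMFit, reduced: GLMFit) -> tuple[float, float]:
    """Likelihood-ratio test for the interaction term.

    Statistic = deviance_reduced - deviance_full (same dispersion), clipped
    at zero when numerical noise makes it marginally negative; p-value from
    the chi-squared(1) upper tail.  Returns (nan, nan) when either fit failed
    to converge or is degenerate.
    """
    if (not full.converged or not reduced.converged
            or full.degenerate or reduced.degenerate):
        return float("nan"), float("nan")
    stat = reduced.deviance - full.deviance
    if stat < 0:
        if stat < -LRT_CLIP_TOL * max(1.0, abs(full.deviance)):
            # genuine violation of nesting indicates a fitting failure
            return float("nan"), float("nan")
        stat = 0.0
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p
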