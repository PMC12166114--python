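"""Single-component mixed model: variance estimation and GBLUP.

Fits y = mu*1 + u + e with u ~ (0, sigma_u^2 K) and e ~ (0, sigma_e^2 I) on
a training subset, by profiling the (restricted) log-likelihood over the
variance ratio r = sigma_u^2 / sigma_e^2.  A single eigendecomposition
K_trn = U D U' reduces every likelihood evaluation to O(n) work, so the
1-D search over log r is cheap.  Predictions for all genotypes are the
GBLUP ghat = sigma_u^2 K[:, trn] (sigma_u^2 K_trn + sigma_e^2 I)^{-1}
(y_trn - mu), returned as mu + ghat.

Also provides a pairwise moment estimator of the genetic covariance between
two traits from single-trait fits of y1, y2 and y1 + y2 — plumbing for
assembling a genetic covariance matrix when no multivariate fit is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from .grm import RelationshipMatrix

__all__ = ["VarianceEstimate", "fit_blup", "pairwise_genetic_covariance"]

# search bounds for log(r), r = varU/varE; hitting a bound is flagged
_LOG_R_BOUNDS = (-10.0, 10.0)
_BRENT_TOL = 1e-8
# profile range below which varU/varE cannot be told apart (e.g. K = I)
_FLAT_PROFILE_TOL = 1e-6


@dataclass
class VarianceEstimate:
    """Variance components from the single-component mixed model.

    ``h2`` is always sigma_u^2 / (sigma_u^2 + sigma_e^2) computed from the
    two estimates.  ``boundary`` is set when the optimizer stopped at a
    bound of the log-ratio search interval.  A criterion that is constant
    over the whole interval (genetic and residual variance not separable,
    e.g. K = I) raises instead of returning an arbitrary split.
    """

    varU: float
    varE: float
    h2: float
    intercept: float
    loglik: float
    method: str = "REML"
    boundary: bool = False


def _profile_criterion(log_r: float, d: np.ndarray, y_rot: np.ndarray,
                       x_rot: np.ndarray, reml: bool) -> tuple[float, float, float]:
    """Negative profile (restricted) log-likelihood at a given log ratio.

    Returns (criterion, mu, varE) with mu and varE profiled out in closed
    form.  Rotated quantities: d eigenvalues of K_trn, y_rot = U'y,
    x_rot = U'1.
    """
    r = np.exp(log_r)
    w = 1.0 / (r * d + 1.0)  # proportional to inverse variance
    xwx = float(np.sum(w * x_rot * x_rot))
    mu = float(np.sum(w * x_rot * y_rot) / xwx)
    e = y_rot - mu * x_rot
    rss = float(np.sum(w * e * e))
    n = d.shape[0]
    logdet = float(np.sum(np.log(r * d + 1.0)))
    if reml:
        df = n - 1
        varE = rss / df
        crit = 0.5 * (df * np.log(varE) + logdet + np.log(xwx) + df)
    else:
        varE = rss / n
        crit = 0.5 * (n * np.log(varE) + logdet + n)
    return crit, mu, varE


def fit_blup(
    y: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    trn: np.ndarray | None = None,
    method: Literal["REML", "ML"] = "REML",
) -> tuple[VarianceEstimate, np.ndarray]:
    """Estimate (varU, varE, mu) on the training subset and predict all genotypes.

    Parameters
    ----------
    y
        Phenotype vector of length n; entries outside ``trn`` may be NaN.
    K
        Relationship matrix covering all n genotypes.
    trn
        Indices of training records.  Defaults to all non-NaN entries of y.
    method
        "REML" (default) or "ML" profile criterion.

    Returns
    -------
    (VarianceEstimate, predictions)
        Predictions are mu + ghat for all n genotypes, including training
        ones.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    y = np.asarray(y, dtype=np.float64)
    n_all = Kv.shape[0]
    if y.shape[0] != n_all:
        raise ValueError("y length does not match K dimension")
    if trn is None:
        trn = np.nonzero(~np.isnan(y))[0]
    trn = np.asarray(trn, dtype=np.intp)
    if np.any(np.isnan(y[trn])):
        raise ValueError("training subset contains missing phenotypes")
    n = trn.shape[0]
    if n < 10:
        raise ValueError(f"training set too small ({n} < 10)")
    y_trn = y[trn]
    if np.var(y_trn) == 0:
        raise ValueError("zero phenotypic variance in training data")

    K_trn = Kv[np.ix_(trn, trn)]
    d, U = np.linalg.eigh(K_trn)
    if d[0] < -1e-8 * max(1.0, d[-1]):
        raise ValueError("K restricted to the training set is not PSD")
    d = np.clip(d, 0.0, None)
    y_rot = U.T @ y_trn
    x_rot = U.T @ np.ones(n)

    reml = method == "REML"
    neg = lambda lr: _profile_criterion(lr, d, y_rot, x_rot, reml)[0]

    lo, hi = _LOG_R_BOUNDS
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": _BRENT_TOL})
    log_r = float(res.x)
    crit, mu, varE = _profile_criterion(log_r, d, y_rot, x_rot, reml)

    # flat-profile / boundary diagnostics
    probe = np.array([neg(lr) for lr in np.linspace(lo, hi, 9)])
    flat = float(probe.max() - probe.min()) < _FLAT_PROFILE_TOL * max(1.0, abs(crit))
    boundary = (log_r - lo < 1e-3) or (hi - log_r < 1e-3)
    if flat:
        raise ValueError(
            "profile criterion is flat in the variance ratio: genetic and "
            "residual variances are not identifiable for this K (e.g. K = I)"
        )

    r = float(np.exp(log_r))
    varU = r * varE
    h2 = varU / (varU + varE)
    est = VarianceEstimate(
        varU=varU, varE=varE, h2=h2, intercept=mu, loglik=-crit,
        method=method, boundary=boundary,
    )

    # BLUP via the same eigenbasis: (varU K_trn + varE I)^{-1} (y - mu)
    inv_rot = (y_rot - mu * x_rot) / (varU * d + varE)
    rhs = U @ inv_rot
    ghat = varU * (Kv[:, trn] @ rhs)
    predictions = mu + ghat
    return est, predictions


def pairwise_genetic_covariance(
    y1: np.ndarray,
    y2: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    method: Literal["REML", "ML"] = "REML",
) -> float:
    """Moment estimator of the genetic covariance between two traits.

    Uses cov(u1, u2) = [var(u1 + u2) - var(u1) - var(u2)] / 2 with each
    genetic variance estimated by a single-trait ``fit_blup`` on the common
    genotype set (records where both traits are observed).
    """
    y1 = np.asarray(y1, dtype=np.float64)
    y2 = np.asarray(y2, dtype=np.float64)
    if y1.shape != y2.shape:
        raise ValueError("traits must be measured on the same genotype vector")
    common = np.nonzero(~np.isnan(y1) & ~np.isnan(y2))[0]
    est1, _ = fit_blup(y1, K, trn=common, method=method)
    est2, _ = fit_blup(y2, K, trn=common, method=method)
    est12, _ = fit_blup(y1 + y2, K, trn=common, method=method)
    return 0.5 * (est12.varU - est1.varU - est2.varU)
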