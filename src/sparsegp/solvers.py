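"""Penalized quadratic solvers operating on sufficient statistics.

All solvers in this package consume the pair (Sigma, Gamma) — the predictor
(co)variance matrix and the predictor-response covariance — instead of raw
data (X, y).  The problem solved is

    beta_hat = argmin_beta  1/2 beta' Sigma beta - beta' Gamma + lambda F(beta)

with the Elastic-Net penalty F(beta) = alpha * sum|beta_j|
+ (1 - alpha)/2 * sum beta_j^2.  Working on sufficient statistics is what
lets the same solver serve ordinary penalized regression, selection indices
(Sigma = Px, Gamma = Gxy) and sparse genomic prediction
(Sigma = P_trn, Gamma = G_trn,tst).

Two routes are provided: cyclic coordinate descent with covariance updates
(`solve_elastic_net`, any alpha) and a LARS homotopy for the full LASSO path
(`lars_path`).  The solvers never rescale Sigma or Gamma — callers own any
1/n scaling convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numba import njit
from scipy import sparse as sp

__all__ = [
    "SufficientStatistics",
    "PenaltyConfig",
    "CoefficientPath",
    "soft_threshold",
    "lambda_max",
    "make_lambda_grid",
    "solve_elastic_net",
    "lars_path",
    "DEFAULT_TOL",
    "DEFAULT_MAXITER",
    "DEFAULT_NLAMBDA",
    "DEFAULT_MIN_RATIO",
    "ALPHA_FLOOR",
]

#: convergence tolerance on the maximum absolute coefficient change per sweep
DEFAULT_TOL = 1e-4
#: maximum coordinate-descent sweeps per lambda
DEFAULT_MAXITER = 1000
#: default size of the automatically generated lambda grid
DEFAULT_NLAMBDA = 100
#: smallest grid lambda as a fraction of lambda_max
DEFAULT_MIN_RATIO = 1e-4
#: surrogate mixing weight used only to size the grid when alpha == 0
#: (pure ridge has no finite lambda_max)
ALPHA_FLOOR = 1e-3

_SYM_TOL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SufficientStatistics:
    """The pair (Sigma, Gamma) driving every solver call.

    Parameters
    ----------
    Sigma
        Symmetric p x p predictor (co)variance matrix.
    Gamma
        p x m covariance between predictors and m response columns.  A
        1-D vector is accepted and treated as a single column.
    """

    Sigma: np.ndarray
    Gamma: np.ndarray

    def __post_init__(self) -> None:
        self.Sigma = np.asarray(self.Sigma, dtype=np.float64)
        G = np.asarray(self.Gamma, dtype=np.float64)
        if G.ndim == 1:
            G = G[:, None]
        self.Gamma = G
        if self.Sigma.ndim != 2 or self.Sigma.shape[0] != self.Sigma.shape[1]:
            raise ValueError("Sigma must be a square matrix")
        p = self.Sigma.shape[0]
        if self.Gamma.shape[0] != p:
            raise ValueError(
                f"Gamma has {self.Gamma.shape[0]} rows, expected {p} (Sigma dimension)"
            )
        scale = max(1.0, float(np.abs(self.Sigma).max()))
        if np.abs(self.Sigma - self.Sigma.T).max() > _SYM_TOL * scale:
            raise ValueError("Sigma must be symmetric (within numeric tolerance)")
        # exact symmetrization so downstream linear algebra sees one matrix
        self.Sigma = 0.5 * (self.Sigma + self.Sigma.T)
        if np.any(np.diag(self.Sigma) <= 0):
            raise ValueError("Sigma must have strictly positive diagonal entries")

    @property
    def p(self) -> int:
        return self.Sigma.shape[0]

    @property
    def n_responses(self) -> int:
        return self.Gamma.shape[1]


@dataclass
class PenaltyConfig:
    """Elastic-Net penalty configuration.

    ``alpha`` mixes the L1 (alpha=1, LASSO) and L2 (alpha=0, ridge) norms.
    ``lambdas`` is a strictly decreasing grid of penalty strengths; when
    None, a 100-value log-spaced grid from lambda_max is generated per
    response column at solve time.
    """

    alpha: float = 1.0
    lambdas: np.ndarray | Sequence[float] | None = None
    nlambda: int = DEFAULT_NLAMBDA
    min_ratio: float = DEFAULT_MIN_RATIO
    tol: float = DEFAULT_TOL
    maxiter: int = DEFAULT_MAXITER

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.maxiter < 1:
            raise ValueError("maxiter must be a positive integer")
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=np.float64)
            if lam.ndim != 1 or lam.size == 0:
                raise ValueError("lambdas must be a non-empty 1-D sequence")
            if np.any(lam < 0):
                raise ValueError("lambdas must be non-negative")
            if lam.size > 1 and np.any(np.diff(lam) >= 0):
                raise ValueError("lambdas must be strictly decreasing")
            self.lambdas = lam


@dataclass
class CoefficientPath:
    """Solutions beta_hat(lambda) along a decreasing lambda grid.

    ``coefficients[k]`` is a sparse p x m matrix (CSC) with the solution for
    every response column at ``lambdas[k]``.
    """

    lambdas: np.ndarray
    coefficients: list[sp.csc_matrix]
    iterations: np.ndarray
    converged: np.ndarray
    alpha: float = 1.0
    response_lambdas: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)

    @property
    def p(self) -> int:
        return self.coefficients[0].shape[0]

    @property
    def n_responses(self) -> int:
        return self.coefficients[0].shape[1]

    def dense(self) -> np.ndarray:
        """Return the full path as an (n_lambda, p, m) dense array."""
        return np.stack([np.asarray(c.todense()) for c in self.coefficients])

    def coef(self, lambda_index: int, response: int = 0) -> np.ndarray:
        """Dense coefficient vector for one grid point and response column."""
        return np.asarray(
            self.coefficients[lambda_index][:, response].todense()
        ).ravel()

    def nonzero_counts(self) -> np.ndarray:
        """Number of non-zero coefficients per (lambda, response)."""
        return np.array(
            [(np.abs(c.toarray()) > 0).sum(axis=0) for c in self.coefficients]
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def soft_threshold(z: float, t: float) -> float:
    """Soft-thresholding operator sign(z) * max(|z| - t, 0).

    The building block of the coordinate-descent update; ``t`` must be
    non-negative.
    """
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def lambda_max(Gamma_col: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which the Elastic-Net solution is all-zero.

    From the KKT conditions at beta = 0, every coordinate stays at zero iff
    |Gamma_j| <= lambda * alpha, so lambda_max = max_j |Gamma_j| / alpha.
    For alpha = 0 (pure ridge, never exactly sparse) the surrogate
    ``ALPHA_FLOOR`` is used purely to size a sensible grid.
    """
    g = np.asarray(Gamma_col, dtype=np.float64).ravel()
    gmax = float(np.abs(g).max()) if g.size else 0.0
    if gmax == 0.0:
        raise ValueError("Gamma column is all zero: degenerate input")
    a = alpha if alpha > 0 else ALPHA_FLOOR
    return gmax / a


def make_lambda_grid(
    lam_max: float,
    nlambda: int = DEFAULT_NLAMBDA,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> np.ndarray:
    """Log-equally-spaced decreasing lambda grid.

    Returns ``nlambda`` values from ``lam_max`` down to
    ``lam_max * min_ratio``; the first element equals ``lam_max`` exactly.
    """
    if nlambda < 2:
        raise ValueError("nlambda must be >= 2")
    if not 0.0 < min_ratio < 1.0:
        raise ValueError("min_ratio must lie in (0, 1)")
    if lam_max <= 0:
        raise ValueError("lam_max must be positive")
    grid = lam_max * np.logspace(0.0, np.log10(min_ratio), nlambda)
    grid[0] = lam_max
    return grid


# ---------------------------------------------------------------------------
# coordinate descent (covariance updates)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cd_path(Sigma, gamma, lambdas, alpha, tol, maxiter):  # pragma: no cover
    """Coordinate-descent path for one response column, warm-started.

    Maintains sb = Sigma @ beta so each coordinate update costs O(p).
    After the active set stabilizes, sweeps run over the active set only,
    with a full sweep to certify convergence.
    """
    p = Sigma.shape[0]
    nl = lambdas.shape[0]
    beta = np.zeros(p)
    sb = np.zeros(p)  # Sigma @ beta, kept in sync
    path = np.zeros((nl, p))
    iters = np.zeros(nl, dtype=np.int64)
    conv = np.zeros(nl, dtype=np.bool_)
    for k in range(nl):
        lam = lambdas[k]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        it = 0
        converged = False
        while it < maxiter:
            # full sweep
            delta_max = 0.0
            for j in range(p):
                rho = gamma[j] - sb[j] + Sigma[j, j] * beta[j]
                if rho > l1:
                    bj = (rho - l1) / (Sigma[j, j] + l2)
                elif rho < -l1:
                    bj = (rho + l1) / (Sigma[j, j] + l2)
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    sb += Sigma[:, j] * d
                    ad = abs(d)
                    if ad > delta_max:
                        delta_max = ad
            it += 1
            if delta_max < tol:
                converged = True
                break
            # inner sweeps restricted to the current active set
            active = np.nonzero(beta)[0]
            while it < maxiter:
                delta_max = 0.0
                for idx in range(active.shape[0]):
                    j = active[idx]
                    rho = gamma[j] - sb[j] + Sigma[j, j] * beta[j]
                    if rho > l1:
                        bj = (rho - l1) / (Sigma[j, j] + l2)
                    elif rho < -l1:
                        bj = (rho + l1) / (Sigma[j, j] + l2)
                    else:
                        bj = 0.0
                    d = bj - beta[j]
                    if d != 0.0:
                        beta[j] = bj
                        sb += Sigma[:, j] * d
                        ad = abs(d)
                        if ad > delta_max:
                            delta_max = ad
                it += 1
                if delta_max < tol:
                    break  # active set converged; certify with a full sweep
        path[k] = beta
        iters[k] = it
        conv[k] = converged
    return path, iters, conv


def solve_elastic_net(
    stats: SufficientStatistics,
    penalty: PenaltyConfig | None = None,
    warm_start: bool = True,
) -> CoefficientPath:
    """Elastic-Net solutions over a lambda grid by cyclic coordinate descent.

    For each response column of ``stats.Gamma`` and each lambda, minimizes
    1/2 b'Sigma b - b'Gamma + lambda [alpha * ||b||_1 + (1-alpha)/2 ||b||_2^2]
    using covariance-form coordinate updates

        b_j <- S(Gamma_j - sum_{k != j} Sigma_jk b_k, lambda*alpha)
               / (Sigma_jj + lambda*(1-alpha))

    warm-starting along the decreasing grid.  Convergence is declared when
    the maximum absolute coefficient change within a sweep drops below
    ``penalty.tol``; non-convergence at ``maxiter`` is flagged per lambda,
    not fatal.

    Returns
    -------
    CoefficientPath
        When ``penalty.lambdas`` is None the grid is generated per response
        column from its own lambda_max; ``path.lambdas`` then holds the
        first column's grid and ``path.response_lambdas`` the full per-column
        grids (all of common length).
    """
    penalty = penalty or PenaltyConfig()
    Sigma = stats.Sigma
    Gamma = stats.Gamma
    p, m = Gamma.shape

    _check_pd_warning(Sigma)

    if penalty.lambdas is not None:
        grids = np.tile(np.asarray(penalty.lambdas, dtype=np.float64), (m, 1))
    else:
        grids = np.empty((m, penalty.nlambda))
        for c in range(m):
            lmax = lambda_max(Gamma[:, c], penalty.alpha)
            grids[c] = make_lambda_grid(lmax, penalty.nlambda, penalty.min_ratio)

    nl = grids.shape[1]
    dense = np.zeros((nl, p, m))
    iters = np.zeros((nl, m), dtype=np.int64)
    conv = np.zeros((nl, m), dtype=bool)
    for c in range(m):
        if warm_start:
            path_c, it_c, cv_c = _cd_path(
                Sigma, np.ascontiguousarray(Gamma[:, c]), grids[c],
                penalty.alpha, penalty.tol, penalty.maxiter,
            )
        else:
            # cold start: solve each lambda from beta = 0 independently
            path_c = np.zeros((nl, p))
            it_c = np.zeros(nl, dtype=np.int64)
            cv_c = np.zeros(nl, dtype=bool)
            for k in range(nl):
                pk, ik, ck = _cd_path(
                    Sigma, np.ascontiguousarray(Gamma[:, c]), grids[c, k: k + 1],
                    penalty.alpha, penalty.tol, penalty.maxiter,
                )
                path_c[k], it_c[k], cv_c[k] = pk[0], ik[0], ck[0]
        dense[:, :, c] = path_c
        iters[:, c] = it_c
        conv[:, c] = cv_c

    # lambda = 0 grid points: direct linear solve for exactness (GBLUP case)
    for k in range(nl):
        if np.all(grids[:, k] == 0.0):
            dense[k] = np.linalg.solve(Sigma, Gamma)
            conv[k] = True

    coefficients = [sp.csc_matrix(dense[k]) for k in range(nl)]
    return CoefficientPath(
        lambdas=grids[0].copy(),
        coefficients=coefficients,
        iterations=iters,
        converged=conv,
        alpha=penalty.alpha,
        response_lambdas=grids if penalty.lambdas is None and m > 1 else None,
    )


def _check_pd_warning(Sigma: np.ndarray) -> None:
    """Warn (not raise) when Sigma is not positive definite.

    Coordinate descent only needs a positive diagonal, but a non-PD Sigma
    means the quadratic form is not strictly convex and solutions may not be
    unique.
    """
    try:
        np.linalg.cholesky(Sigma + 0.0)
    except np.linalg.LinAlgError:
        warnings.warn(
            "Sigma is not positive definite; coordinate descent proceeds but "
            "the penalized problem may lack a unique minimizer",
            RuntimeWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# LARS homotopy (full LASSO path)
# ---------------------------------------------------------------------------


def lars_path(
    stats: SufficientStatistics,
    method: Literal["LASSO", "LAR"] = "LASSO",
) -> CoefficientPath:
    """Least-angle-regression path from sufficient statistics.

    Computes the breakpoints {lambda_max = l1 > l2 > ... > 0} of the
    piecewise-linear LASSO solution path and the exact solution at each
    breakpoint.  On the segment with active set A and signs s, the solution
    is the affine function

        beta_A(lambda) = Sigma_AA^{-1} (Gamma_A - lambda * s_A)

    so candidate events (an inactive variable reaching the correlation bound
    |c_j(lambda)| = lambda, or — with method="LASSO" — an active coefficient
    crossing zero) are roots of scalar affine functions.  The final point
    (lambda = 0) is the unpenalized solution Sigma^{-1} Gamma.

    ``method="LAR"`` disables the LASSO drop step, giving plain least-angle
    regression where variables only ever enter.

    Ties in the entry condition are broken by the lowest predictor index.
    Requires a single response column; solve multiple columns one at a time.
    """
    if method not in ("LASSO", "LAR"):
        raise ValueError("method must be 'LASSO' or 'LAR'")
    if stats.n_responses != 1:
        raise ValueError("lars_path handles one response column at a time")
    Sigma = stats.Sigma
    gamma = stats.Gamma[:, 0]
    p = Sigma.shape[0]

    if np.all(gamma == 0):
        raise ValueError("Gamma is all zero: degenerate input")

    # perfectly collinear predictor pairs make the path non-unique: raise
    # rather than guess
    d = np.sqrt(np.diag(Sigma))
    corr = Sigma / np.outer(d, d)
    dup = np.abs(corr) >= 1.0 - 1e-12
    np.fill_diagonal(dup, False)
    if dup.any():
        i, j = np.argwhere(dup)[0]
        raise np.linalg.LinAlgError(
            f"predictors {i} and {j} are perfectly collinear in Sigma; "
            "the LASSO path is not unique"
        )

    lam = lambda_max(gamma, alpha=1.0)
    lambdas = [lam]
    betas = [np.zeros(p)]

    # lowest-index tie-break on entry at lambda_max
    at_max = np.abs(np.abs(gamma) - lam) <= 1e-12 * max(1.0, lam)
    j0 = int(np.nonzero(at_max)[0][0])
    active: list[int] = [j0]
    signs: dict[int, float] = {j0: float(np.sign(gamma[j0]))}

    eps = 1e-12
    max_steps = 8 * p + 10
    for _ in range(max_steps):
        A = np.array(active, dtype=np.intp)
        sA = np.array([signs[j] for j in active])
        SAA = Sigma[np.ix_(A, A)]
        _check_active_pd(SAA, A)
        # beta_A(l) = a - l * b on this segment
        a = np.linalg.solve(SAA, gamma[A])
        b = np.linalg.solve(SAA, sA)

        inactive = np.setdiff1d(np.arange(p), A, assume_unique=False)
        # c_j(l) = u_j + l * v_j for inactive j
        u = gamma[inactive] - Sigma[np.ix_(inactive, A)] @ a
        v = Sigma[np.ix_(inactive, A)] @ b

        best_lam = 0.0
        best_event: tuple[str, int, float] | None = None

        # entry events: c_j(l) = +l  =>  l = u/(1-v);  c_j(l) = -l  =>  l = -u/(1+v)
        for sign_target in (1.0, -1.0):
            denom = sign_target - v
            with np.errstate(divide="ignore", invalid="ignore"):
                cand = np.where(np.abs(denom) > eps, u / denom, -np.inf)
            for idx in np.argsort(inactive):  # lowest index preference on ties
                j = int(inactive[idx])
                lj = float(cand[idx])
                if eps < lj < lam * (1 - 1e-10):
                    if lj > best_lam * (1 + 1e-10):
                        best_lam, best_event = lj, ("enter", j, sign_target)

        if method == "LASSO":
            # drop events: a_j - l b_j = 0 => l = a_j / b_j
            for pos, j in enumerate(active):
                if abs(b[pos]) > eps:
                    lj = float(a[pos] / b[pos])
                    if eps < lj < lam * (1 - 1e-10) and lj > best_lam * (1 + 1e-10):
                        best_lam, best_event = lj, ("drop", j, 0.0)

        if best_event is None:
            # no event before lambda reaches 0: close the path
            beta_end = np.zeros(p)
            beta_end[A] = a
            lambdas.append(0.0)
            betas.append(beta_end)
            break

        lam = best_lam
        beta_k = np.zeros(p)
        beta_k[A] = a - lam * b
        kind, j, sign_target = best_event
        if kind == "enter":
            active.append(j)
            signs[j] = sign_target
        else:
            beta_k[j] = 0.0  # exact zero at the crossing
            active.remove(j)
            del signs[j]
        lambdas.append(lam)
        betas.append(beta_k)
    else:
        raise RuntimeError("LARS exceeded the maximum number of path steps")

    lam_arr = np.array(lambdas)
    coefficients = [sp.csc_matrix(b[:, None]) for b in betas]
    n = len(lambdas)
    return CoefficientPath(
        lambdas=lam_arr,
        coefficients=coefficients,
        iterations=np.arange(n, dtype=np.int64)[:, None],
        converged=np.ones((n, 1), dtype=bool),
        alpha=1.0,
    )


def _check_active_pd(SAA: np.ndarray, A: np.ndarray) -> None:
    try:
        np.linalg.cholesky(SAA)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"Sigma is singular on the active set {A.tolist()} "
            "(duplicate or collinear predictors)"
        ) from exc
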