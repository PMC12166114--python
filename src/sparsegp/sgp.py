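"""Sparse selection indices and single/multi-trait sparse genomic prediction.

A genomic prediction for a testing record is a weighted sum of training
phenotypes, ghat_i = w_i' y_trn.  GBLUP uses the dense weights
W = G' P^{-1}; sparse genomic prediction (SGP) instead solves, per testing
record i,

    w_i = argmin_w 1/2 w' P_trn w - w' G_trn,tst(i) + lambda F(w)

so only a subset of training records receives non-zero weight.  In the
single-trait case P_trn = varU * K_trn + varE * I and
G = varU * K_trn,tst; in the multi-trait/environment case the stacked
phenotype vector has covariance (Omega kron K) + (R kron I) and P and G are
sub-matrices of it, indexed by (genotype, trait) maps.  Setting lambda = 0
recovers (MT-)GBLUP exactly.

This module assembles P and G without ever materializing the full Kronecker
product, runs the Elastic-Net path from :mod:`sparsegp.solvers` for every
testing record, and exposes the selection-index problem (`solve_ssi`) which
is the same quadratic program with P = Px (phenotypic covariance of
indicator traits) and G = Gxy (their genetic covariances with the
objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .grm import RelationshipMatrix
from .solvers import (
    CoefficientPath,
    PenaltyConfig,
    SufficientStatistics,
    lambda_max,
    make_lambda_grid,
    solve_elastic_net,
)
from .varcomp import fit_blup

__all__ = [
    "StackedPhenotypeIndex",
    "CovParams",
    "SGPResult",
    "build_P",
    "build_G",
    "sgp_solve",
    "solve_ssi",
    "predict_index",
    "predict_from_weights",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StackedPhenotypeIndex:
    """Maps each stacked phenotype record to a genotype and a trait.

    ``ID_geno[r]`` is the row of K and ``ID_trait[r]`` the index into
    Omega/R for record r (0-based internally; file formats are 1-based).
    ``trn`` and ``tst`` are disjoint record index sets.
    """

    ID_geno: np.ndarray
    ID_trait: np.ndarray
    trn: np.ndarray
    tst: np.ndarray

    def __post_init__(self) -> None:
        self.ID_geno = np.asarray(self.ID_geno, dtype=np.intp)
        self.ID_trait = np.asarray(self.ID_trait, dtype=np.intp)
        self.trn = np.asarray(self.trn, dtype=np.intp)
        self.tst = np.asarray(self.tst, dtype=np.intp)
        if self.ID_geno.shape != self.ID_trait.shape or self.ID_geno.ndim != 1:
            raise ValueError("ID_geno and ID_trait must be 1-D and equal length")
        nrec = self.ID_geno.shape[0]
        pairs = set(zip(self.ID_geno.tolist(), self.ID_trait.tolist()))
        if len(pairs) != nrec:
            raise ValueError("duplicate (genotype, trait) record pairs")
        for name, idx in (("trn", self.trn), ("tst", self.tst)):
            if idx.size and (idx.min() < 0 or idx.max() >= nrec):
                raise ValueError(f"{name} record indices out of range")
        if np.intersect1d(self.trn, self.tst).size:
            raise ValueError("trn and tst overlap")

    @property
    def n_records(self) -> int:
        return self.ID_geno.shape[0]

    @property
    def n_traits(self) -> int:
        return int(self.ID_trait.max()) + 1 if self.n_records else 0

    @classmethod
    def complete(
        cls,
        n_geno: int,
        n_traits: int,
        trn: Sequence[int] | None = None,
        tst: Sequence[int] | None = None,
    ) -> "StackedPhenotypeIndex":
        """Complete trait-major grid: records (g=0..n-1) for trait 0, then 1, ...

        Record r = t * n_geno + g, mirroring the stacking
        y = (y_1', ..., y_q')'.
        """
        geno = np.tile(np.arange(n_geno), n_traits)
        trait = np.repeat(np.arange(n_traits), n_geno)
        trn_a = np.asarray(trn if trn is not None else np.arange(n_geno * n_traits))
        tst_a = np.asarray(tst if tst is not None else [], dtype=np.intp)
        if trn is None and tst is not None:
            trn_a = np.setdiff1d(np.arange(n_geno * n_traits), tst_a)
        return cls(geno, trait, trn_a, tst_a)

    def subset(self, records: np.ndarray, trn: np.ndarray, tst: np.ndarray
               ) -> "StackedPhenotypeIndex":
        """Restrict to a record subset, renumbering records to 0..len-1.

        ``trn``/``tst`` are given in the original record numbering and must
        be subsets of ``records``.
        """
        records = np.asarray(records, dtype=np.intp)
        pos = {int(r): i for i, r in enumerate(records)}
        return StackedPhenotypeIndex(
            self.ID_geno[records],
            self.ID_trait[records],
            np.array([pos[int(r)] for r in trn], dtype=np.intp),
            np.array([pos[int(r)] for r in tst], dtype=np.intp),
        )


@dataclass
class CovParams:
    """Within-genotype genetic (Omega) and error (R) covariance across traits."""

    Omega: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.Omega = np.atleast_2d(np.asarray(self.Omega, dtype=np.float64))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=np.float64))
        for name, M in (("Omega", self.Omega), ("R", self.R)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square")
            if np.abs(M - M.T).max() > 1e-8 * max(1.0, float(np.abs(M).max())):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(M) <= 0):
                raise ValueError(f"{name} must have positive diagonal entries")
        if self.Omega.shape != self.R.shape:
            raise ValueError("Omega and R must have the same dimension q")
        self.Omega = 0.5 * (self.Omega + self.Omega.T)
        self.R = 0.5 * (self.R + self.R.T)

    @property
    def q(self) -> int:
        return self.Omega.shape[0]


@dataclass
class SGPResult:
    """Sparse per-testing-record weights over a lambda grid.

    ``weights[k]`` is a sparse n_tst x n_trn matrix W(lambda_k); row i holds
    the training weights of testing record i.  ``nsup[k]`` is the average
    number of non-zero weights per testing record at lambda_k, recomputed
    from the stored weights.
    """

    lambdas: np.ndarray
    weights: list[sp.csr_matrix]
    index: StackedPhenotypeIndex
    nsup: np.ndarray = field(init=False)
    lambda_opt: float | None = None
    intercepts: np.ndarray | None = None
    predictions: np.ndarray | None = None
    converged: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=np.float64)
        self.nsup = np.array(
            [float((np.abs(W.toarray()) > 0).sum(axis=1).mean()) if W.shape[0] else 0.0
             for W in self.weights]
        )

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)

    @property
    def n_tst(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_trn(self) -> int:
        return self.weights[0].shape[1]

    def predict(self, y: np.ndarray) -> np.ndarray:
        """Predictions per lambda from a full stacked phenotype vector.

        Training phenotypes are centered by the per-trait intercepts (when
        present) and the intercept of each testing record's trait is added
        back: ghat_tst(lambda) = mu_tst + W(lambda) (y_trn - mu_trn).
        """
        y = np.asarray(y, dtype=np.float64)
        y_trn = y[self.index.trn]
        if np.any(np.isnan(y_trn)):
            raise ValueError("training records contain missing phenotypes")
        if self.intercepts is not None:
            mu_trn = self.intercepts[self.index.ID_trait[self.index.trn]]
            mu_tst = self.intercepts[self.index.ID_trait[self.index.tst]]
        else:
            mu_trn = 0.0
            mu_tst = 0.0
        centered = y_trn - mu_trn
        return np.stack([mu_tst + W @ centered for W in self.weights])


# ---------------------------------------------------------------------------
# covariance assembly (no full Kronecker product)
# ---------------------------------------------------------------------------


def _as_K(K: RelationshipMatrix | np.ndarray) -> np.ndarray:
    return K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)


def build_P(
    K: RelationshipMatrix | np.ndarray,
    cov: CovParams,
    index: StackedPhenotypeIndex,
    rows: np.ndarray,
    cols: np.ndarray,
) -> np.ndarray:
    """Sub-matrix of var(y) = (Omega kron K) + (R kron I) for given records.

    Entry (i, j) is Omega[t_i, t_j] * K[g_i, g_j] + R[t_i, t_j] * 1(g_i = g_j)
    — computed directly from the index maps, never materializing the
    Kronecker product.
    """
    Kv = _as_K(K)
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    gr, tr = index.ID_geno[rows], index.ID_trait[rows]
    gc, tc = index.ID_geno[cols], index.ID_trait[cols]
    _check_cov_index(Kv, cov, gr, tr, gc, tc)
    P = cov.Omega[np.ix_(tr, tc)] * Kv[np.ix_(gr, gc)]
    P += cov.R[np.ix_(tr, tc)] * (gr[:, None] == gc[None, :])
    return P


def build_G(
    K: RelationshipMatrix | np.ndarray,
    Omega: np.ndarray,
    index: StackedPhenotypeIndex,
    rows: np.ndarray,
    cols: np.ndarray,
) -> np.ndarray:
    """Sub-matrix of the genetic covariance Omega kron K for given records."""
    Kv = _as_K(K)
    Omega = np.atleast_2d(np.asarray(Omega, dtype=np.float64))
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    gr, tr = index.ID_geno[rows], index.ID_trait[rows]
    gc, tc = index.ID_geno[cols], index.ID_trait[cols]
    q = Omega.shape[0]
    if (tr.size and tr.max() >= q) or (tc.size and tc.max() >= q):
        raise IndexError("trait index exceeds Omega dimension")
    if (gr.size and gr.max() >= Kv.shape[0]) or (gc.size and gc.max() >= Kv.shape[0]):
        raise IndexError("genotype index exceeds K dimension")
    return Omega[np.ix_(tr, tc)] * Kv[np.ix_(gr, gc)]


def _check_cov_index(Kv, cov, gr, tr, gc, tc) -> None:
    q = cov.q
    if (tr.size and tr.max() >= q) or (tc.size and tc.max() >= q):
        raise IndexError("trait index exceeds Omega/R dimension q")
    n = Kv.shape[0]
    if (gr.size and gr.max() >= n) or (gc.size and gc.max() >= n):
        raise IndexError("genotype index exceeds K dimension")


# ---------------------------------------------------------------------------
# the SGP solve
# ---------------------------------------------------------------------------


def sgp_solve(
    K: RelationshipMatrix | np.ndarray,
    index: StackedPhenotypeIndex,
    cov: CovParams | None = None,
    y: np.ndarray | None = None,
    penalty: PenaltyConfig | None = None,
    intercepts: np.ndarray | None = None,
) -> SGPResult:
    """Solve the sparse-genomic-prediction problem for every testing record.

    Builds Sigma = P over trn x trn and Gamma = G over trn x tst once, then
    runs the Elastic-Net path per testing record over a single lambda grid
    shared by all records (sized from the largest per-record lambda_max).
    Grid points with lambda = 0 are solved by a direct symmetric solve so
    the (MT-)GBLUP special case W = G' P^{-1} is exact.

    Parameters
    ----------
    cov
        Omega and R.  May be omitted only in the single-trait case with
        ``y`` supplied; varU, varE and the intercept are then estimated
        from the training records via :func:`sparsegp.varcomp.fit_blup`.
    y
        Full stacked phenotype vector; when given, per-lambda predictions
        ghat_tst(lambda) = mu + W(lambda)(y_trn - mu) are included in the
        result.
    intercepts
        Per-trait intercepts used to center training phenotypes.  Default:
        the fit_blup intercept when cov is estimated, otherwise the
        arithmetic per-trait training means (all zero if y is None).
    """
    Kv = _as_K(K)
    penalty = penalty or PenaltyConfig()
    trn, tst = index.trn, index.tst
    if trn.size == 0 or tst.size == 0:
        raise ValueError("both trn and tst must be non-empty")

    q = index.n_traits
    if cov is None:
        if q != 1:
            raise ValueError("cov (Omega, R) is required for multi-trait data")
        if y is None:
            raise ValueError("cov omitted: y is required to estimate variances")
        geno_trn = index.ID_geno[trn]
        y_geno = np.full(Kv.shape[0], np.nan)
        y_geno[geno_trn] = np.asarray(y, float)[trn]
        est, _ = fit_blup(y_geno, Kv, trn=geno_trn)
        cov = CovParams(np.array([[est.varU]]), np.array([[est.varE]]))
        if intercepts is None:
            intercepts = np.array([est.intercept])

    if intercepts is None and y is not None:
        y_arr = np.asarray(y, dtype=np.float64)
        intercepts = np.zeros(cov.q)
        t_trn = index.ID_trait[trn]
        for t in range(cov.q):
            mask = t_trn == t
            if mask.any():
                intercepts[t] = float(np.mean(y_arr[trn][mask]))

    Sigma = build_P(Kv, cov, index, trn, trn)
    Gamma = build_G(Kv, cov.Omega, index, trn, tst)

    if penalty.lambdas is not None:
        lambdas = np.asarray(penalty.lambdas, dtype=np.float64)
    else:
        lmax = max(lambda_max(Gamma[:, c], penalty.alpha)
                   for c in range(Gamma.shape[1]))
        lambdas = make_lambda_grid(lmax, penalty.nlambda, penalty.min_ratio)

    shared = PenaltyConfig(
        alpha=penalty.alpha, lambdas=lambdas,
        tol=penalty.tol, maxiter=penalty.maxiter,
    )
    path = solve_elastic_net(SufficientStatistics(Sigma, Gamma), shared)

    # lambda = 0 grid points were already solved directly inside the solver;
    # recompute here with a Cholesky solve for numerical symmetry either way
    zero_idx = np.nonzero(lambdas == 0.0)[0]
    dense_zero = None
    if zero_idx.size:
        c, low = cho_factor(Sigma)
        dense_zero = cho_solve((c, low), Gamma)

    weights: list[sp.csr_matrix] = []
    for k in range(len(lambdas)):
        if dense_zero is not None and lambdas[k] == 0.0:
            Wk = sp.csr_matrix(dense_zero.T)
        else:
            Wk = sp.csr_matrix(path.coefficients[k].T)
        weights.append(Wk)

    result = SGPResult(
        lambdas=lambdas,
        weights=weights,
        index=index,
        intercepts=intercepts,
        converged=path.converged,
        provenance={
            "alpha": penalty.alpha,
            "tol": penalty.tol,
            "maxiter": penalty.maxiter,
            "n_trn": int(trn.size),
            "n_tst": int(tst.size),
        },
    )
    if y is not None:
        result.predictions = result.predict(np.asarray(y, dtype=np.float64))
    return result


# ---------------------------------------------------------------------------
# selection index and prediction helpers
# ---------------------------------------------------------------------------


def solve_ssi(
    Px: np.ndarray,
    Gxy: np.ndarray,
    penalty: PenaltyConfig | None = None,
) -> CoefficientPath:
    """Sparse selection index: penalized weights for indicator traits.

    Solves argmin_w 1/2 w' Px w - w' Gxy + lambda F(w) where Px is the
    phenotypic covariance of the measured traits and Gxy their genetic
    covariances with the selection objective.  lambda = 0 gives the
    classical Smith-Hazel index w = Px^{-1} Gxy.
    """
    return solve_elastic_net(SufficientStatistics(Px, Gxy), penalty)


def predict_index(path: CoefficientPath, X: np.ndarray, response: int = 0
                  ) -> np.ndarray:
    """Apply selection-index weights to candidate trait records.

    Returns an (n_lambda, n_candidates) array ghat(lambda) = X w(lambda).
    """
    X = np.asarray(X, dtype=np.float64)
    return np.stack([X @ path.coef(k, response) for k in range(path.n_lambda)])


def predict_from_weights(
    result: SGPResult | Sequence[sp.spmatrix],
    y_trn: np.ndarray,
) -> np.ndarray:
    """Raw weighted sums W(lambda) y_trn, one row per lambda.

    This is the pure sparse matrix-vector product on whatever scale
    ``y_trn`` is given (no intercept handling); use
    :meth:`SGPResult.predict` for intercept-aware predictions.
    """
    weights = result.weights if isinstance(result, SGPResult) else list(result)
    y_trn = np.asarray(y_trn, dtype=np.float64)
    n_trn = weights[0].shape[1]
    if y_trn.shape[0] != n_trn:
        raise ValueError(
            f"y_trn has length {y_trn.shape[0]}, expected {n_trn} training records"
        )
    return np.stack([np.asarray(W @ y_trn).ravel() for W in weights])
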