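"""SGP layer: Kronecker subsetting against a brute-force oracle, GBLUP
special cases, single/multi-trait decoupling, selection indices and weight
application."""

import numpy as np
import pytest
from scipy import sparse as sp

import sparsegp as sg
from sparsegp.sgp import build_G, build_P


def kron_oracle(Omega, K, R, n, q):
    """Fully materialized var(y) = (Omega kron K) + (R kron I)."""
    return np.kron(Omega, K) + np.kron(R, np.eye(n))


# ---------------------------------------------------------------------------
# index bookkeeping
# ---------------------------------------------------------------------------


def test_index_validation():
    with pytest.raises(ValueError, match="duplicate"):
        sg.StackedPhenotypeIndex([0, 0], [1, 1], [0], [1])
    with pytest.raises(ValueError, match="overlap"):
        sg.StackedPhenotypeIndex([0, 1], [0, 0], [0, 1], [1])
    with pytest.raises(ValueError, match="out of range"):
        sg.StackedPhenotypeIndex([0, 1], [0, 0], [0], [5])


def test_complete_index_is_trait_major():
    idx = sg.StackedPhenotypeIndex.complete(3, 2, tst=[4])
    np.testing.assert_array_equal(idx.ID_geno, [0, 1, 2, 0, 1, 2])
    np.testing.assert_array_equal(idx.ID_trait, [0, 0, 0, 1, 1, 1])
    assert 4 not in idx.trn and idx.trn.size == 5


# ---------------------------------------------------------------------------
# P and G assembly
# ---------------------------------------------------------------------------


def test_build_P_hand_example():
    Omega = np.array([[1.0, 0.5], [0.5, 1.0]])
    R = np.eye(2)
    K = np.eye(2)
    idx = sg.StackedPhenotypeIndex.complete(2, 2, tst=[])
    all_recs = np.arange(4)
    cov = sg.CovParams(Omega, R)
    P = build_P(K, cov, idx, all_recs, all_recs)
    # record order (trait-major): (g1,t1), (g2,t1), (g1,t2), (g2,t2)
    assert P[0, 2] == pytest.approx(0.5)  # same genotype, traits 1x2
    assert P[0, 1] == pytest.approx(0.0)  # different genotypes, same trait
    assert P[0, 0] == pytest.approx(2.0)  # Omega_11*K_11 + R_11


def test_single_trait_P_reduces_to_classic_form(st_sim):
    varU, varE = 0.4, 0.6
    cov = sg.CovParams([[varU]], [[varE]])
    n = st_sim.K.n
    idx = sg.StackedPhenotypeIndex.complete(n, 1, tst=[])
    P = build_P(st_sim.K, cov, idx, np.arange(n), np.arange(n))
    np.testing.assert_allclose(P, varU * st_sim.K.values + varE * np.eye(n),
                               atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_subsets_match_brute_force_kronecker(seed):
    """Random incomplete-data index sets must reproduce sub-matrices of the
    fully materialized Kronecker covariance (n <= 10, q <= 3)."""
    rng = np.random.default_rng(seed)
    n, q = int(rng.integers(4, 11)), int(rng.integers(2, 4))
    A = rng.standard_normal((n, 2 * n))
    K = A @ A.T / (2 * n)
    B = rng.standard_normal((q, q))
    Omega = B @ B.T + 0.1 * np.eye(q)
    C = rng.standard_normal((q, q))
    R = C @ C.T + 0.1 * np.eye(q)
    cov = sg.CovParams(Omega, R)
    idx = sg.StackedPhenotypeIndex.complete(n, q, tst=[])
    full = kron_oracle(Omega, K, R, n, q)
    G_full = np.kron(Omega, K)
    nrec = n * q
    rows = rng.choice(nrec, size=rng.integers(2, nrec), replace=False)
    cols = rng.choice(nrec, size=rng.integers(2, nrec), replace=False)
    np.testing.assert_allclose(build_P(K, cov, idx, rows, cols),
                               full[np.ix_(rows, cols)], atol=1e-12)
    np.testing.assert_allclose(build_G(K, Omega, idx, rows, cols),
                               G_full[np.ix_(rows, cols)], atol=1e-12)


def test_build_G_diagonal_Omega_zeroes_cross_trait():
    K = np.array([[1.0, 0.3], [0.3, 1.0]])
    idx = sg.StackedPhenotypeIndex.complete(2, 2, tst=[])
    G = build_G(K, np.diag([0.4, 0.5]), idx, np.arange(4), np.arange(4))
    assert G[0, 2] == 0.0 and G[1, 3] == 0.0
    np.testing.assert_allclose(G[:2, :2], 0.4 * K)


def test_build_errors():
    K = np.eye(3)
    idx = sg.StackedPhenotypeIndex.complete(3, 2, tst=[])
    cov = sg.CovParams(np.eye(2), np.eye(2))
    with pytest.raises(IndexError):
        build_P(K, sg.CovParams(np.eye(1), np.eye(1)), idx,
                np.arange(6), np.arange(6))
    with pytest.raises(ValueError, match="dimension"):
        sg.CovParams(np.eye(2), np.eye(3))
    del cov


def test_removing_training_record_is_pure_subsetting(mt_sim):
    """Dropping one training record must not change P or G restricted to
    the remaining records."""
    cov = sg.CovParams(mt_sim.config.Omega, mt_sim.config.R)
    idx = mt_sim.index
    recs = idx.trn[:20]
    P_full = build_P(mt_sim.K, cov, idx, recs, recs)
    kept = np.delete(recs, 7)
    P_sub = build_P(mt_sim.K, cov, idx, kept, kept)
    keep_pos = np.delete(np.arange(20), 7)
    np.testing.assert_array_equal(P_sub, P_full[np.ix_(keep_pos, keep_pos)])


# ---------------------------------------------------------------------------
# sgp_solve
# ---------------------------------------------------------------------------


def _split(n, n_tst, seed=0):
    rng = np.random.default_rng(seed)
    tst = np.sort(rng.choice(n, size=n_tst, replace=False))
    trn = np.setdiff1d(np.arange(n), tst)
    return trn, tst


def test_st_lambda0_equals_fit_blup(st_sim):
    n = st_sim.K.n
    trn, tst = _split(n, 30, seed=1)
    idx = sg.StackedPhenotypeIndex.complete(n, 1, trn=trn, tst=tst)
    y_masked = np.where(np.isin(np.arange(n), trn), st_sim.y, np.nan)
    est, blup = sg.fit_blup(y_masked, st_sim.K, trn=trn)
    res = sg.sgp_solve(st_sim.K, idx, y=st_sim.y,
                       penalty=sg.PenaltyConfig(lambdas=np.array([0.0])))
    assert np.abs(res.predictions[0] - blup[tst]).max() < 1e-6


def test_mt_lambda0_equals_direct_solve(mt_sim):
    cov = sg.CovParams(mt_sim.config.Omega, mt_sim.config.R)
    n, q = mt_sim.config.n, mt_sim.config.q
    rng = np.random.default_rng(3)
    tst = np.sort(rng.choice(n * q, size=25, replace=False))
    trn = np.setdiff1d(np.arange(n * q), tst)
    idx = sg.StackedPhenotypeIndex.complete(n, q, trn=trn, tst=tst)
    res = sg.sgp_solve(mt_sim.K, idx, cov=cov, y=mt_sim.y,
                       penalty=sg.PenaltyConfig(lambdas=np.array([0.0])),
                       intercepts=np.zeros(q))
    P = build_P(mt_sim.K, cov, idx, trn, trn)
    G = build_G(mt_sim.K, cov.Omega, idx, trn, tst)
    direct = G.T @ np.linalg.solve(P, mt_sim.y[trn])
    assert np.abs(res.predictions[0] - direct).max() < 1e-6


def test_lambda_above_max_gives_zero_weights(st_sim):
    n = st_sim.K.n
    trn, tst = _split(n, 10, seed=2)
    idx = sg.StackedPhenotypeIndex.complete(n, 1, trn=trn, tst=tst)
    res = sg.sgp_solve(st_sim.K, idx, cov=sg.CovParams([[0.4]], [[0.6]]),
                       y=st_sim.y,
                       penalty=sg.PenaltyConfig(lambdas=np.array([10.0])),
                       intercepts=np.zeros(1))
    assert res.weights[0].nnz == 0
    assert res.nsup[0] == 0.0
    np.testing.assert_array_equal(res.predictions[0], 0.0)


def test_default_grid_largest_lambda_zeroes_all_records(st_sim):
    n = st_sim.K.n
    trn, tst = _split(n, 15, seed=4)
    idx = sg.StackedPhenotypeIndex.complete(n, 1, trn=trn, tst=tst)
    res = sg.sgp_solve(st_sim.K, idx, cov=sg.CovParams([[0.4]], [[0.6]]),
                       penalty=sg.PenaltyConfig(nlambda=20))
    assert res.weights[0].nnz == 0  # shared grid starts at the max lambda_max
    assert res.n_lambda == 20
    assert res.predictions is None


def test_mt_diagonal_covariances_decouple_into_st(mt_sim):
    """With diagonal Omega and R the multi-trait system is block-diagonal,
    so per-trait weights must equal the single-trait solve on that trait
    alone (same lambda grid)."""
    n, q = 50, 3
    Omega = np.diag([0.5, 0.4, 0.6])
    R = np.diag([0.5, 0.6, 0.4])
    sim = sg.simulate_multitrait(sg.SimConfig(
        n=n, p_or_m=200, q=q, Omega=Omega, R=R, seed=21))
    rng = np.random.default_rng(10)
    tst_g = np.sort(rng.choice(n, size=8, replace=False))
    tst = np.concatenate([t * n + tst_g for t in range(q)])
    trn = np.setdiff1d(np.arange(n * q), tst)
    idx = sg.StackedPhenotypeIndex.complete(n, q, trn=trn, tst=tst)
    lambdas = sg.make_lambda_grid(1.0, 30, 1e-3)
    pen = sg.PenaltyConfig(alpha=1.0, lambdas=lambdas, tol=1e-10)
    mt = sg.sgp_solve(sim.K, idx, cov=sg.CovParams(Omega, R), penalty=pen)

    trn_traits = idx.ID_trait[trn]
    tst_traits = idx.ID_trait[tst]
    for t in range(q):
        trn_g = idx.ID_geno[trn[trn_traits == t]]
        st_idx = sg.StackedPhenotypeIndex.complete(
            n, 1, trn=trn_g, tst=tst_g)
        st = sg.sgp_solve(sim.K, st_idx,
                          cov=sg.CovParams([[Omega[t, t]]], [[R[t, t]]]),
                          penalty=pen)
        rows = np.nonzero(tst_traits == t)[0]
        cols = np.nonzero(trn_traits == t)[0]
        for k in range(len(lambdas)):
            W_mt = mt.weights[k].toarray()[np.ix_(rows, cols)]
            W_st = st.weights[k].toarray()
            assert np.abs(W_mt - W_st).max() < 1e-8
            # cross-trait weights are exactly zero
            other = np.setdiff1d(np.arange(len(trn)), cols)
            assert np.abs(mt.weights[k].toarray()[np.ix_(rows, other)]).max() == 0


def test_genotype_relabeling_equivariance(st_sim):
    n = st_sim.K.n
    trn, tst = _split(n, 12, seed=5)
    idx = sg.StackedPhenotypeIndex.complete(n, 1, trn=trn, tst=tst)
    cov = sg.CovParams([[0.4]], [[0.6]])
    pen = sg.PenaltyConfig(lambdas=sg.make_lambda_grid(0.5, 10, 1e-2))
    res = sg.sgp_solve(st_sim.K, idx, cov=cov, y=st_sim.y, penalty=pen)

    perm = np.random.default_rng(6).permutation(n)
    K_perm = st_sim.K.values[np.ix_(perm, perm)]
    inv = np.argsort(perm)  # genotype g now sits at row inv[g]
    idx_perm = sg.StackedPhenotypeIndex(inv[idx.ID_geno], idx.ID_trait,
                                        trn, tst)
    res_perm = sg.sgp_solve(K_perm, idx_perm, cov=cov, y=st_sim.y,
                            penalty=pen)
    np.testing.assert_allclose(res_perm.predictions, res.predictions,
                               atol=1e-10)


def test_nsup_dense_at_lambda0(st_sim):
    n = st_sim.K.n
    trn, tst = _split(n, 10, seed=7)
    idx = sg.StackedPhenotypeIndex.complete(n, 1, trn=trn, tst=tst)
    res = sg.sgp_solve(st_sim.K, idx, cov=sg.CovParams([[0.4]], [[0.6]]),
                       penalty=sg.PenaltyConfig(lambdas=np.array([0.0])))
    assert res.nsup[0] == len(trn)


def test_sgp_errors(st_sim):
    n = st_sim.K.n
    idx = sg.StackedPhenotypeIndex.complete(n, 1, tst=[])
    with pytest.raises(ValueError, match="non-empty"):
        sg.sgp_solve(st_sim.K, idx, cov=sg.CovParams([[0.4]], [[0.6]]))
    trn, tst = _split(n, 10)
    idx2 = sg.StackedPhenotypeIndex.complete(n, 1, trn=trn, tst=tst)
    with pytest.raises(ValueError, match="estimate"):
        sg.sgp_solve(st_sim.K, idx2)  # no cov, no y


# ---------------------------------------------------------------------------
# selection index
# ---------------------------------------------------------------------------


def test_ssi_lambda0_is_smith_hazel(rng):
    p = 6
    A = rng.standard_normal((40, p))
    Px = A.T @ A / 40
    Gxy = rng.standard_normal(p) * 0.3
    path = sg.solve_ssi(Px, Gxy, sg.PenaltyConfig(lambdas=np.array([0.0])))
    np.testing.assert_allclose(path.coef(0), np.linalg.solve(Px, Gxy),
                               atol=1e-10)


def test_ssi_orthonormal_soft_threshold():
    path = sg.solve_ssi(np.eye(3), np.array([0.3, 0.0, 0.1]),
                        sg.PenaltyConfig(alpha=1.0, lambdas=np.array([0.2])))
    np.testing.assert_allclose(path.coef(0), [0.1, 0.0, 0.0], atol=1e-10)


def test_index_variance_decreases_with_lambda(rng):
    """var(X w(lambda)) shrinks monotonically as the penalty grows."""
    n, p = 300, 10
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:3] = [0.8, 0.5, 0.3]
    y = X @ beta + rng.standard_normal(n)
    Px = X.T @ X / n
    Gxy = X.T @ y / n
    path = sg.solve_ssi(Px, Gxy, sg.PenaltyConfig(alpha=1.0, nlambda=30,
                                                  tol=1e-8))
    ghat = sg.predict_index(path, X)
    variances = ghat.var(axis=1)
    assert np.all(np.diff(variances) >= -1e-10)  # lambda grid is decreasing


# ---------------------------------------------------------------------------
# weight application
# ---------------------------------------------------------------------------


def test_predict_from_weights_examples(st_sim):
    W0 = sp.csr_matrix(np.zeros((2, 5)))
    W1 = sp.csr_matrix(np.array([[0, 0, 1.0, 0, 0], [0, 0, 0, 0, 0]]))
    y = np.arange(5.0)
    out = sg.predict_from_weights([W0, W1], y)
    np.testing.assert_array_equal(out[0], [0.0, 0.0])
    np.testing.assert_array_equal(out[1], [2.0, 0.0])
    with pytest.raises(ValueError, match="length"):
        sg.predict_from_weights([W0], np.ones(3))


def test_predict_from_weights_matches_dense(rng):
    W = sp.random(6, 40, density=0.2, random_state=1, format="csr")
    y = rng.standard_normal(40)
    np.testing.assert_allclose(sg.predict_from_weights([W], y)[0],
                               W.toarray() @ y, atol=1e-12)
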