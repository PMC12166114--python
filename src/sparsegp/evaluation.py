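"""Training-testing partitions, accuracy, and cross-validated lambda choice.

The CV2 partitioning scheme evaluates prediction of genotypes that are
observed for some traits/environments but predicted for others: n0
genotypes are sampled, and for each a random pair of traits is withheld as
testing data, so n_tst = 2 * n0 and the remaining n*q - n_tst records
train the model.  Accuracy is always the within-trait Pearson correlation
between observed and predicted testing values.  The regularization
parameter lambda is chosen by k-fold cross-validation carried out entirely
inside the training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grm import RelationshipMatrix
from .sgp import CovParams, SGPResult, StackedPhenotypeIndex, build_G, sgp_solve
from .solvers import PenaltyConfig, make_lambda_grid

__all__ = [
    "PartitionSpec",
    "CVReport",
    "PARTITION_PRESETS",
    "cv2_partition",
    "accuracy_by_trait",
    "kfold_cv_lambda",
    "nsup_summary",
    "bias_slope",
]

logger = logging.getLogger(__name__)


@dataclass
class PartitionSpec:
    """Specification of a CV2 training-testing partition.

    ``n0`` genotypes each contribute ``pair_size`` randomly chosen
    trait/environment records to the testing set; everything else trains.
    ``trait_pool`` optionally restricts the traits from which the withheld
    pair is drawn (used when testing is confined to one trait category of a
    larger grid).
    """

    n: int
    q: int
    n0: int
    pair_size: int = 2
    seed: int = 0
    trait_pool: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("CV2 needs at least 2 traits/environments")
        if not 0 < self.n0 <= self.n:
            raise ValueError("n0 must satisfy 0 < n0 <= n")
        pool = range(self.q) if self.trait_pool is None else self.trait_pool
        pool = sorted(int(t) for t in pool)
        if any(t < 0 or t >= self.q for t in pool):
            raise ValueError("trait_pool indices out of range")
        if self.pair_size > len(pool):
            raise ValueError("pair_size exceeds the number of eligible traits")
        self.trait_pool = pool


#: named layouts of the benchmark datasets (genotypes, traits, testing
#: genotypes); rice categories test within a pool of a 20-trait grid
PARTITION_PRESETS: Mapping[str, PartitionSpec] = {
    "wheat": PartitionSpec(n=3731, q=4, n0=2238),
    "maize_north": PartitionSpec(n=4132, q=4, n0=2478),
    "maize_south": PartitionSpec(n=1868, q=4, n0=1116),
    "rice_morphology": PartitionSpec(n=413, q=20, n0=240, trait_pool=range(0, 4)),
    "rice_yield_components": PartitionSpec(
        n=413, q=20, n0=360, trait_pool=range(4, 10)),
    "rice_seed_morphology": PartitionSpec(
        n=413, q=20, n0=300, trait_pool=range(10, 15)),
    "rice_quality": PartitionSpec(n=413, q=20, n0=180, trait_pool=range(15, 18)),
}


def cv2_partition(spec: PartitionSpec) -> StackedPhenotypeIndex:
    """Draw a CV2 partition of the complete n x q record grid.

    Samples ``spec.n0`` genotypes without replacement; for each, an
    unordered pair (``pair_size`` distinct traits) from the trait pool is
    withheld for testing.  Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n, spec.q
    genos = rng.choice(n, size=spec.n0, replace=False)
    pool = np.asarray(spec.trait_pool, dtype=np.intp)
    tst_records = np.empty(spec.n0 * spec.pair_size, dtype=np.intp)
    for i, g in enumerate(genos):
        traits = rng.choice(pool, size=spec.pair_size, replace=False)
        # trait-major stacking: record = t * n + g
        tst_records[i * spec.pair_size: (i + 1) * spec.pair_size] = traits * n + g
    tst_records = np.sort(tst_records)
    trn_records = np.setdiff1d(np.arange(n * q), tst_records)
    return StackedPhenotypeIndex.complete(n, q, trn=trn_records, tst=tst_records)


def accuracy_by_trait(
    y_tst: np.ndarray,
    g_hat: np.ndarray,
    ID_trait_tst: np.ndarray,
) -> dict[int, float]:
    """Within-trait Pearson correlation of observed and predicted values.

    Traits with fewer than 3 testing records, or with zero variance in
    either vector, get NaN.
    """
    y_tst = np.asarray(y_tst, dtype=np.float64)
    g_hat = np.asarray(g_hat, dtype=np.float64)
    ID_trait_tst = np.asarray(ID_trait_tst, dtype=np.intp)
    if not y_tst.shape == g_hat.shape == ID_trait_tst.shape:
        raise ValueError("y_tst, g_hat and ID_trait_tst must have equal length")
    out: dict[int, float] = {}
    for t in np.unique(ID_trait_tst):
        mask = ID_trait_tst == t
        if mask.sum() < 3:
            out[int(t)] = np.nan
            continue
        yv, gv = y_tst[mask], g_hat[mask]
        if np.std(yv) == 0 or np.std(gv) == 0:
            out[int(t)] = np.nan
            continue
        out[int(t)] = float(np.corrcoef(yv, gv)[0, 1])
    return out


@dataclass
class CVReport:
    """k-fold cross-validation profile of accuracy against lambda.

    ``accuracy[k, t]`` is the mean (over folds) within-trait correlation at
    lambda_k for trait t; ``mean_accuracy`` averages across traits.
    ``lambda_opt`` maximizes the mean accuracy, ties resolved toward the
    larger (sparser) lambda.
    """

    lambdas: np.ndarray
    accuracy: np.ndarray
    mean_accuracy: np.ndarray
    lambda_opt: float
    lambda_opt_index: int
    folds: list[np.ndarray]
    seed: int
    trait_ids: np.ndarray = field(default_factory=lambda: np.array([]))


def _stratified_folds(
    records: np.ndarray, traits: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal each trait's records round-robin into k folds after shuffling."""
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for t in np.unique(traits):
        recs = records[traits == t]
        recs = rng.permutation(recs)
        for i, r in enumerate(recs):
            folds[(i + offset) % k].append(int(r))
        offset += recs.size  # stagger so fold sizes stay balanced overall
    return [np.sort(np.array(f, dtype=np.intp)) for f in folds]


def kfold_cv_lambda(
    y: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    cov: CovParams,
    index: StackedPhenotypeIndex,
    k: int = 10,
    seed: int = 0,
    penalty: PenaltyConfig | None = None,
) -> CVReport:
    """Choose lambda by k-fold cross-validation within the training records.

    Only ``index.trn`` is ever used — testing records never inform the
    choice of lambda.  Each fold in turn becomes pseudo-testing for an SGP
    solved on the remaining folds over one shared lambda grid; within-trait
    correlations are averaged per fold across traits, then across folds.

    A fold contributing fewer than 3 records of some trait has that trait
    omitted from its average (logged).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    penalty = penalty or PenaltyConfig()
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    trn = index.trn
    traits_trn = index.ID_trait[trn]
    folds = _stratified_folds(trn, traits_trn, k, rng)

    # one lambda grid shared by all folds, sized from the largest
    # per-pseudo-record lambda_max across folds
    if penalty.lambdas is not None:
        lambdas = np.asarray(penalty.lambdas, dtype=np.float64)
    else:
        from .solvers import ALPHA_FLOOR

        G_all = build_G(K, cov.Omega, index, trn, trn)
        np.fill_diagonal(G_all, 0.0)  # a record never predicts itself in CV
        alpha_eff = penalty.alpha if penalty.alpha > 0 else ALPHA_FLOOR
        lmax = float(np.abs(G_all).max()) / alpha_eff
        lambdas = make_lambda_grid(lmax, penalty.nlambda, penalty.min_ratio)

    fold_pen = PenaltyConfig(alpha=penalty.alpha, lambdas=lambdas,
                             tol=penalty.tol, maxiter=penalty.maxiter)

    all_traits = np.unique(traits_trn)
    t_pos = {int(t): i for i, t in enumerate(all_traits)}
    acc_sum = np.zeros((len(lambdas), len(all_traits)))
    acc_cnt = np.zeros((len(lambdas), len(all_traits)))

    for f, fold in enumerate(folds):
        pseudo_trn = np.setdiff1d(trn, fold)
        sub = index.subset(trn, trn=pseudo_trn, tst=fold)
        res = sgp_solve(K, sub, cov=cov, y=y[trn], penalty=fold_pen)
        preds = res.predictions  # (n_lambda, len(fold))
        y_fold = y[trn][sub.tst]
        t_fold = sub.ID_trait[sub.tst]
        for t in np.unique(t_fold):
            mask = t_fold == t
            if mask.sum() < 3:
                logger.info("fold %d: trait %d has %d records, omitted",
                            f, int(t), int(mask.sum()))
                continue
            yv = y_fold[mask]
            if np.std(yv) == 0:
                continue
            for kk in range(len(lambdas)):
                gv = preds[kk][mask]
                if np.std(gv) == 0:
                    continue
                acc_sum[kk, t_pos[int(t)]] += float(np.corrcoef(yv, gv)[0, 1])
                acc_cnt[kk, t_pos[int(t)]] += 1

    with np.errstate(invalid="ignore"):
        accuracy = np.where(acc_cnt > 0, acc_sum / np.maximum(acc_cnt, 1), np.nan)
    mean_accuracy = np.nanmean(accuracy, axis=1)
    # ties -> the larger lambda; the grid is decreasing so argmax (first
    # maximal index) already lands on the sparser model
    best = int(np.nanargmax(mean_accuracy))
    return CVReport(
        lambdas=lambdas,
        accuracy=accuracy,
        mean_accuracy=mean_accuracy,
        lambda_opt=float(lambdas[best]),
        lambda_opt_index=best,
        folds=folds,
        seed=seed,
        trait_ids=all_traits,
    )


def nsup_summary(result: SGPResult) -> dict[str, np.ndarray]:
    """Support-size profile of an SGP fit.

    Returns per-lambda average support size (``nsup``) and, per lambda, the
    fraction of non-zero weights that point at training records of each
    trait (``composition``, rows summing to 1 wherever nsup > 0) — the data
    behind sparsity-versus-accuracy area plots.
    """
    traits_trn = result.index.ID_trait[result.index.trn]
    all_traits = np.unique(traits_trn)
    comp = np.zeros((result.n_lambda, len(all_traits)))
    for kk, W in enumerate(result.weights):
        nz_cols = W.tocoo().col[np.abs(W.tocoo().data) > 0]
        if nz_cols.size == 0:
            continue
        t_nz = traits_trn[nz_cols]
        for i, t in enumerate(all_traits):
            comp[kk, i] = float(np.mean(t_nz == t))
    return {
        "lambdas": result.lambdas,
        "nsup": result.nsup,
        "trait_ids": all_traits,
        "composition": comp,
    }


def bias_slope(y_tst: np.ndarray, g_hat: np.ndarray) -> tuple[float, float]:
    """Mean bias and regression slope of observed on predicted values.

    slope = cov(y, ghat) / var(ghat); mean bias = mean(y) - mean(ghat).
    A slope above 1 indicates over-shrunk predictions.
    """
    y_tst = np.asarray(y_tst, dtype=np.float64)
    g_hat = np.asarray(g_hat, dtype=np.float64)
    if np.var(g_hat) == 0:
        raise ValueError("predictions have zero variance: slope undefined")
    slope = float(np.cov(y_tst, g_hat, ddof=1)[0, 1] / np.var(g_hat, ddof=1))
    bias = float(np.mean(y_tst) - np.mean(g_hat))
    return bias, slope
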