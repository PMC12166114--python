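# Methods

## Model

Phenotypes are modelled as `y = μ + g + ε` with genetic values `g` whose
covariance is proportional to a genomic relationship matrix `K`, and
independent residuals. Stacking `q` traits/environments trait-major,
`var(y) = (Ω ⊗ K) + (R ⊗ I)` with `Ω` and `R` the q×q genetic and error
(co)variance matrices across traits. Two (genotype, trait) index vectors
map each record of the stacked vector to a row of `K` and an index of
`Ω`/`R`; incomplete data is handled purely by sub-setting this map — the
covariance of any observed subset is the corresponding sub-matrix of the
Kronecker form, and `build_P`/`build_G` compute those entries directly
(`Ω[tᵢ,tⱼ]·K[gᵢ,gⱼ] + R[tᵢ,tⱼ]·1(gᵢ=gⱼ)`) without materializing `Ω ⊗ K`.

Predictions for a testing record are weighted sums of training phenotypes.
The weights solve, per testing record,
`min_w ½w'P_trn w − w'G_trn,tst(i) + λF(w)` with the Elastic-Net penalty
`F(w) = αΣ|wⱼ| + ½(1−α)Σwⱼ²`. `λ = 0` is (MT-)GBLUP; growing `λ` zeroes
weights, so each prediction equation uses a data subset. The selection-
index problem is the same program with `Σ = Pₓ`, `Γ = G_xy`.

One display in the literature this package follows prints the multi-trait
training covariance as `(R ⊗ K) + (R ⊗ I)`; that is inconsistent with the
stated `var(y) = (Ω ⊗ K) + (R ⊗ I)` and with the single-trait reduction
`σ²ᵤK + σ²εI`, so this package deliberately uses `Ω ⊗ K` in `P`.

## Solvers

Both solvers consume sufficient statistics `(Σ, Γ)` and never rescale
them; whether `Σ, Γ` carry a `1/n` factor is the caller's convention, and
the SGP/SSI layers pass covariance matrices unscaled. This keeps the
special cases exact.

**Coordinate descent** uses the covariance-form update
`βⱼ ← S(Γⱼ − Σ_{k≠j}Σⱼₖβₖ, λα)/(Σⱼⱼ + λ(1−α))` (`S` = soft-thresholding),
warm-started along a decreasing λ grid, with `Σβ` maintained incrementally
so one update costs O(p). After each full sweep, inner sweeps run over the
current active set only; convergence requires a certifying full sweep whose
maximum absolute coefficient change is below `tol` (default `1e-4`,
`maxiter` 1000 sweeps; non-convergence is flagged per λ, never fatal). The
update is the exact per-coordinate minimizer of the objective, so solutions
carry a KKT certificate: `|Γⱼ − (Σβ)ⱼ − λ(1−α)βⱼ| ≤ λα`, with equality and
sign agreement on the support. Grid points with `λ = 0` are solved by a
direct symmetric solve for exactness. A non-positive-definite `Σ` triggers
a warning (coordinate descent only needs a positive diagonal), since the
minimizer may then be non-unique. The kernel is JIT-compiled with numba.

**λ grid.** `λmax = maxⱼ|Γⱼ|/α` is the smallest λ with an all-zero
solution (from the KKT conditions at β=0). The default grid is 100 values,
log-equally spaced from `λmax` down to `10⁻⁴·λmax`. `λ = 0` is *not*
appended by default — GBLUP is requested explicitly — and pure ridge
(α = 0) has no finite λmax, so a surrogate mixing weight of `10⁻³` is used
only to size its grid.

**LARS homotopy.** On a segment with active set A and signs s the LASSO
solution is affine in λ: `β_A(λ) = Σ_AA⁻¹(Γ_A − λs_A)`. Breakpoints are
roots of scalar affine functions — an inactive variable reaching the
correlation bound `|cⱼ(λ)| = λ`, or (LASSO mode) an active coefficient
crossing zero, which drops the variable. `method="LAR"` disables drops.
Entry ties break toward the lowest predictor index; perfectly collinear
predictor pairs raise (the path is not unique) rather than guessing, and a
singular active-set system reports the offending set. The path ends at the
unpenalized solution `Σ⁻¹Γ`. LARS handles one response column at a time.

## GRM

`K = ZZ'/v` from column-centered markers `Z`, with `v = Σⱼ var(z·ⱼ)` using
the method-of-moments variance (denominator n). This denominator is what
makes `mean(diag K) = 1` an exact identity, fixing the scale of `σ²ᵤ`.
Column-mean imputation of missing genotypes is available but off by
default. No alternative scalings (allele-frequency weights, dominance) are
provided.

## Variance components

`fit_blup` fits `y = μ1 + u + ε`, `u ~ (0, σ²ᵤK)`, on the training subset
by eigendecomposing `K_trn = UDU'` once and profiling the criterion over
the ratio `r = σ²ᵤ/σ²ε`: given `r`, the intercept and `σ²ε` have closed
forms in the rotated basis, so the optimization is a 1-D bounded Brent
search on `log r ∈ [−10, 10]` (tolerance `1e-8`; a solution at a bound is
flagged). REML is the default criterion, ML available by flag; the only
fixed effect is an intercept, since phenotypes are assumed pre-adjusted
for non-genetic effects. Missing phenotypes are handled by index
sub-setting, never imputation. With `K = I` the profile criterion is
exactly constant in `r` (genetic and residual variance are not separable);
this is detected by probing the criterion across the interval and raises
rather than returning an arbitrary split. BLUPs for all genotypes use the
same eigenbasis, and `sgp_solve` at `λ = 0` reproduces them to machine
precision.

`pairwise_genetic_covariance` is deliberately simple plumbing:
`cov(u₁,u₂) = [varU(y₁+y₂) − varU(y₁) − varU(y₂)]/2` from three
single-trait fits. Production multi-trait analyses should estimate `Ω`
and `R` with a dedicated multivariate (e.g. Bayesian) fitter and pass
them in as inputs.

## SGP assembly and intercepts

`sgp_solve` builds `Σ = P_trn,trn` and `Γ = G_trn,tst` once and solves all
per-record problems over a **single λ grid shared by all testing records**,
sized from the largest per-record `λmax`. (Per-record grids would be
equally valid; a shared grid is chosen because one λ is reported per model
and `nsup` averages across records.) The per-record problems are
independent and may be solved in any order.

The penalized problem is formulated for centered data. When a phenotype
vector is supplied, training records are centered by per-trait intercepts
and the testing trait's intercept is added back:
`ĝ = μ_t(tst) + W(y_trn − μ_t(trn))`. The intercepts default to the
mixed-model (GLS) intercept when variance components are estimated
internally (single trait), and to arithmetic per-trait training means
otherwise; callers can pass exact values. `predict_from_weights` remains
the raw product `W y_trn` for callers who own the centering.

## Evaluation

`cv2_partition` implements the CV2 scheme: `n0` genotypes sampled without
replacement, each contributing a random unordered pair of trait records to
the testing set (`n_tst = 2n0`); an optional trait pool restricts the pair
to one category of a larger grid. The benchmark layouts ship as named
presets (`PARTITION_PRESETS`). Because the "equal representation" sizing
rule does not uniquely determine `n0`, it stays an explicit parameter.

`kfold_cv_lambda` receives only training records — the testing set cannot
influence λ. Folds are stratified by trait so every fold supports
within-trait correlations; a fold with fewer than three records of a trait
omits that trait from its average (logged). Accuracy is the within-trait
Pearson correlation, averaged per fold across traits (simple mean — no
weighting rule is prescribed, so the simplest is used and documented),
then across folds. Ties in the accuracy profile resolve toward the larger
(sparser) λ. When no grid is supplied, `λmax` is taken from
`max|G_trn,trn|` with the diagonal zeroed, since a record never predicts
itself in cross-validation. `bias_slope` regresses observed on predicted
values (`slope = cov(y, ĝ)/var(ĝ)`); over-shrunk predictions give slopes
above 1.

## Synthetic data

`simulate_regression`: standardized Gaussian predictors; exactly
`round(p·prop_nonzero)` effects drawn from Gamma(4, rate 4) — all positive
by default, with an optional sign flip; error sd = `noise_multiplier` ×
signal sd (defaults n=3000, p=500, 10% non-zero, multiplier 3).

`simulate_multitrait`: doubled-haploid-style {0, 2} marker codes with
allele frequencies uniform on (0.1, 0.5); `K` from `compute_grm`; genetic
values drawn with covariance `Ω ⊗ K` via matrix square roots, residuals
with `R ⊗ I`. Defaults: per-trait genetic variance 0.4 and error variance
0.6 (the single-trait benchmark setting, h² = 0.4), genetic correlation
0.5 across traits — the moderate range reported for grain yield across
environments.

`simulate_family_structured`: 24 families × 8 genotypes; each individual
copies its family founder's haplotype with per-locus resampling
probability 0.1, over 80 markers, and the genetic value is purely a family
effect (varU=0.6, varE=0.4). The modest marker count makes between-family
kinship estimates noisy while within-family relatedness stays high
(mean within-family K ≈ 0.7), so the informative training records for any
candidate are its relatives — the regime where sparse prediction equations
beat dense GBLUP. These sizes were fixed as the package's scaled-down
analogue of a structured breeding population.

None of the generators attempts to mimic the linkage-disequilibrium decay
or population structure of real crop panels; passing tests demonstrate
correctness of the algorithms and the qualitative sparsity behavior, not
expected accuracy levels on real data.

## Numerical choices and problem sizes

- Solver defaults: `tol 1e-4`, `maxiter 1000`, grid of 100 λ values down
  to `10⁻⁴·λmax`; tests that certify optimality tighten `tol` to
  `1e-8`–`1e-12`.
- Test problem sizes are kept at desk scale by design: solver certificates
  on 200 random instances with p ≤ 20; GBLUP equivalences at n = 200;
  Kronecker oracles at n ≤ 10, q ≤ 3; decoupling at n = 50, q = 3;
  variance-component recovery over 20 replicates at n = 1000 genotypes ×
  2000 markers; CV behavior over 20 replicates of the 192-genotype family
  design.
- Degenerate inputs raise informative errors: all-zero `Γ`, zero-variance
  phenotypes or markers, too-small training sets, non-identifiable `K = I`,
  perfectly collinear predictors in LARS.

## Known limitations

- Only additive kernels; no dominance/epistasis/RKHS, and no
  environmental-covariate models.
- `Ω` and `R` are inputs; the built-in pairwise moment estimator is a
  testing convenience, not a substitute for a proper multivariate fit.
- The solvers take sufficient statistics only — there is no raw-data
  (X, y) regression front end with standardization/weights.
- File-based record indices are 1-based; all in-memory indices 0-based.
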