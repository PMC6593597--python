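# Methods

## Model

Tumor/normal status across two pooled disease cohorts is modeled by
logistic regression, P(Y=1|x) = exp(β₀ + xᵀβ)/(1 + exp(β₀ + xᵀβ)),
fitted by minimizing the penalized average negative log-likelihood

    f(β₀, β) = −(1/n) ℓ(β₀, β) + λ[ α‖w∘β‖₁ + (1−α)‖w∘β‖₂² ].

Scaling the likelihood by 1/n makes λ comparable across sample sizes.
The intercept is never penalized. Note the ℓ₂ term is ‖w∘β‖₂² =
Σ (w_j β_j)², i.e. the factor enters the ridge part squared — this is
the exact "penalty applied to the Hadamard product" reading, and it is
what makes the rescaling reparameterization below exact. Solvers in the
glmnet family instead multiply both penalty terms linearly by a
rescaled factor; with factors in [0, 1] and λ always chosen by
cross-validation, the two conventions reorder nothing in practice, but
coefficients at a *fixed* λ are not comparable across conventions.

### Penalty factors

For cohorts A and B, per-gene factors are w_j = d_j / max_k d_k, where
d_j is the angle between gene j's correlation columns in the two
cohorts' Pearson matrices. Choices made where the definition is open:

- **Self-correlation excluded** (default): the diagonal entry is 1 in
  both diseases and would deflate every angle uniformly; a flag
  restores the literal full-column reading.
- **Tumor samples only** (default) define each disease's correlation
  structure, since the penalty targets the disease networks; `all` and
  `normal_only` are available.
- **Angles in degrees** everywhere (the canonical pre-filter threshold
  is 75°); weights are unit-free ratios.
- **Degenerate all-zero distances** (identical correlation matrices)
  make w_j = 0/0; all weights are set to 0 — every gene unpenalized —
  with a loud warning, the only limit consistent with "smaller distance
  → smaller penalty".
- The angle is evaluated as 2·atan2(‖â−b̂‖, ‖â+b̂‖) on the
  normalized columns (Kahan's formula): identical to arccos of the
  clamped cosine in exact arithmetic, but it returns exactly 0 for
  identical columns where arccos loses half its digits. Cosines
  overshooting |1| by more than 1e−12 raise an error.

### Pre-filter

Genes with d_j ≥ 75° (strict `<` keeps, configurable) are discarded
before fitting. Weights are *not* renormalized afterwards: the
max-normalization is defined on the full gene set, and renormalizing
would silently strengthen every surviving penalty.

## Solver

Glmnet-style coordinate descent, written for this package because no
installed Python solver exposes per-feature penalty factors for
logistic elastic net: an outer IRLS quadratic approximation (working
weights floored at 1e−9, probabilities clipped at 1e−9), inner cyclic
coordinate descent with soft-thresholding at λαw_j and curvature
denominator Σv_i x_ij²/n + 2λ(1−α)w_j². Convergence is declared on the
KKT residual of the *true* objective (< 10·tol, tol default 1e−7; 1e5
sweep budget), not just on coefficient stagnation. A second route
rescales x̃_j = x_j/w_j (w_j > 0), solves the standard elastic net, and
maps back β_j = β̃_j/w_j; the two routes agree to ~1e−8 in objective
and serve as mutual checks in the test suite, with scikit-learn's saga
solver as an independent reference for the unit-weight case. w_j = 0
exempts a gene from shrinkage entirely; with complete separation and
all w_j > 0 the penalty keeps the optimum finite.

λ paths descend log-spaced from λ_max = max_j |x_jᵀ(y−ȳ)|/(n·α·w_j)
(the KKT threshold at which everything is zero; α floored at 1e−3 for
the ridge end) over 100 values to 1e−3·λ_max, warm-started.
Cross-validation (default 10-fold, stratified by class whenever every
class has ≥ k members, else plain shuffled folds) scores each λ by
held-out Brier score (or deviance) and takes the minimizer, ties going
to the larger (sparser) λ. Fold assignment derives from an explicit
seed.

## Protocol

`run_stability` repeats, for run r with seed base_seed + r: a
stratified 75/25 train/test split (stratification is a choice — with
tumor:normal ≈ 9:1 an unstratified test set can lose the normal class;
a flag disables it), then for each method (EN = unit factors, twiner =
angular factors; both share the split, so the comparison is paired and
the EN arm is literally the same code path) 10-fold CV for λ at
α = 0.9, a refit, and train/test Brier score, PR-AUC,
misclassification count at cutoff 0.5 (probability exactly at the
cutoff calls positive), and the selected gene set. Aggregates: per-gene
selection frequencies, consensus = frequency strictly > 0.75, medians
of each metric, and the EN-only/shared/twiner-only Venn decomposition.
"MSE of classification" is the Brier score on probabilities; a
hard-label variant sits behind a flag. PR-AUC uses step-wise
interpolation with tied scores grouped (average-precision form).

Correlation networks for selected genes are exported as edge lists
(gene_i, gene_j, r, sign, |r|), computed on tumor or normal samples.

## Survival validation

A signature is validated on tumor samples by a joint Cox
proportional-hazards fit on its genes (Breslow ties; a small ridge
term, default 1e−4, stabilizes wide signatures against few events — 0
forces the unpenalized fit), relative risk exp(xᵀβ̂), a median split
with the exact-median sample (and any ties) assigned to the low-risk
group, Kaplan–Meier curves per group, and the two-group log-rank test
against χ²(1). Constant fitted risks (e.g. a null signature shrunk to
β̂ = 0) cannot be stratified and raise an error rather than returning
an arbitrary p-value. All-censored tables are rejected (≥ 2 events
required).

## Synthetic data

`TwinScenario` draws Gaussian expression at the post-preprocessing
scale (log-FPKM z-scores are approximately Gaussian, so simulating
after the transform is faithful and avoids a count model); a lognormal
mode exponentiates the draws to exercise `preprocess`. Correlated
blocks are one-factor: x_j = s_j√ρ·f + √(1−ρ)·ε_j with signs s_j = ±1,
giving corr = s_i s_j ρ. The twin block keeps identical loadings in
both cohorts; each disease-specific block re-signs a random half of its
loadings (and permutes their order) in cohort B, which drives those
genes' correlation columns nearly orthogonal between cohorts. Labels
are Bernoulli(logistic(β₀ + effect·Σ_signal x_j)) with β₀ set from the
tumor fraction. Defaults — 150 samples/cohort, 300 genes, one 30-gene
twin block, two 30-gene specific blocks, ρ = 0.7, 5 signal genes in the
twin block with effect 1.0 on the log-odds, tumor fraction 0.85
(mirroring the heavy tumor:normal imbalance of TCGA cohorts) — are
sized so the full resampling protocol runs in minutes on one CPU.
Survival times are exponential with rate baseline·exp(Σ coef·x) and
independent exponential censoring.

What the generator does **not** emulate: count noise and
library-size effects, batch structure, heavy-tailed expression,
block-overlapping pathway structure, and realistic censoring patterns.
Passing tests demonstrate the estimator and protocol behave as designed
under the stated Gaussian conditions, not performance on real RNA-Seq.

## Preprocessing

`preprocess` applies log(x + offset) (natural log, offset 1 — the
common pseudo-count convention for FPKM; both configurable) then
per-gene z-scores with the n−1 sample standard deviation.
Zero-variance genes are dropped and reported (their correlations are
undefined). Cohorts are merged over the gene-identifier intersection in
the first cohort's order.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the protocol at the
default scenario (300 genes, 150 samples per cohort) with 20–30
resampling runs per invocation and 3 generator seeds for the recovery
check — enough replication for the paired comparisons while keeping a
full run in minutes on a single core.

## Known limitations

- Pearson correlation only; no partial correlations or mutual
  information.
- The Cox validation fits all signature genes jointly (optionally
  ridge-stabilized); it is not a regularized Cox selection.
- Penalty factors follow the exact Hadamard-product objective (see
  above); coefficients at fixed λ differ from glmnet-convention
  solvers even though selections under CV match.
- No plotting: networks, Venn memberships and KM curves are emitted as
  tables.
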