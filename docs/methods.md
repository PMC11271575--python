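# Methods

This note documents the model, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Model

All quantities live on the standardized genotype scale: genotype
columns are centered and scaled to unit variance, so a marginal GWAS
effect is r ≈ corr(SNP, trait) and the LD matrix R is a correlation
matrix with unit diagonal. The individual-level penalized least-squares
problem for M populations is approximated with summary statistics by
substituting XᵀX/n → R (from an external reference panel) and
Xᵀy/n → r, giving the objective

Σᵢ [βᵢᵀ(Rᵢ + δᵢI)βᵢ − 2βᵢᵀrᵢ + 2λᵢ‖βᵢ‖₁] + Σ_{i₁<i₂} c_{i₁i₂}‖βᵢ₁^s − βᵢ₂^s‖₂²

- the lasso penalty acts per population and produces sparse solutions;
- the ridge penalty acts on *differences* of effect sizes at SNPs
  shared by a pair of populations, encoding the empirical observation
  that causal effects are strongly (but not perfectly) correlated
  across ancestries; unlike a fused lasso it allows small differences
  instead of truncating them to zero;
- δᵢ regularizes the sampling noise of the reference LD matrix;
- a SNP common in only one population carries no ridge term (lasso
  only); membership is data-driven (harmonization + MAF > 0.01 on the
  reference panel).

Because R is block-diagonal over LD blocks and the penalties are
SNP-separable, blocks can be solved independently; this is asserted
against a joint oracle in the tests, not assumed.

### Coordinate descent

Exact coordinate minimization has the closed form

βᵢₖ ← sign(uᵢₖ)·max(0, |uᵢₖ| − λᵢ) / (1 + δᵢ + Σ_{i′: k shared} c_{ii′}),
uᵢₖ = rᵢₖ − Σ_{k′≠k} R_{i,k′k}βᵢₖ′ + Σ_{i′: k shared} c_{ii′}βᵢ′ₖ

with the diagonal of R taken as exactly 1. Updates cycle
population-major then in SNP order (deterministic). Convergence: max
absolute coefficient change < 1e-7, capped at 1000 sweeps per block.
Divergence safeguards: a (λ, c) cell is flagged if any |β| exceeds
10·max|r|/λ_min or the objective rises on 3 consecutive sweeps; flagged
cells are excluded from the ensemble but retained with their flag.
Exact coordinate minimization of a convex objective cannot increase it,
so the per-sweep objective trace is checked to be non-increasing (up to
1e-9 relative floating-point slack) in the acceptance suite.

Warm starts run along the λ path (descending) within each c; they are a
speedup, not a different estimator — a test verifies warm- and
cold-started solutions agree at tight tolerance.

### Extreme fusion (c → ∞)

Cyclic coordinate descent contracts the pair-difference mode at rate
≈ (c/(1+c))² per sweep, so at c = 1e6 it cannot reach the fused
solution from a cold start within any reasonable sweep budget. The
fusion-limit checks therefore use warm-started continuation along an
increasing c ladder (geometric, 1 → 1e6), the standard homotopy remedy;
it reaches the pooled soft-threshold solution to ~1e-4. The production
c path only spans [2, 100], where plain descent converges comfortably.

### Penalty grids

- Single-ancestry (reference) grid: δ ∈ {0.001, 0.01, 0.1, 1}; λ — 30
  values log-spaced from 0.01·max|r| to max|r|. The tuning-data optimum
  (δ⁰, λ⁰) is selected by validation metric (R² or AUC), ties broken
  toward larger λ (sparser model). If tuning data exist only for the
  target population, every population's path is scored on the target
  cohort ("tuning-on-target").
- Joint grid: λᵢ = λ·λᵢ⁰ with the scale factor λ on 10 log-spaced
  values from λ_max = minᵢ(max_k|rᵢₖ|/λᵢ⁰) down to 0.001·λ_max (the
  upper end guarantees a nonzero solution for the population attaining
  the min); c on 10 values evenly spaced on a quad-root scale from 2 to
  100; δᵢ fixed at δᵢ⁰ and never re-tuned. A 5×5 "reduced" preset is
  available via `grid_lengths`/CLI flags. An optional distance-scaling
  factor r ∈ {0.5, 1, 1.5} multiplies c for pairs involving one
  designated (genetically distant) population.

### Ensemble

Stacking on the target tuning cohort. Base learners (all linear in the
candidate scores): for continuous traits a lasso path (100 penalties,
inner 5-fold CV), a ridge path (penalties 1 to 20 by 0.1) and OLS; for
binary traits an L1-penalized and an unpenalized logistic regression
(ridge omitted for binary traits). Candidates are standardized with the
exact back-transformation recorded, and exactly duplicated columns are
deduplicated before the penalized fits. Out-of-fold predictions from a
10-fold split (stratified for binary; fold seed recorded) feed the
meta-learner: non-negative least squares normalized to the simplex for
continuous traits, simplex-grid AUC maximization for binary. Refitting
the base learners on the full tuning set and combining with the
meta-weights yields effective per-candidate weights, which collapse to
per-SNP weights w_k = Σ w_{λ,c,i}·β_{λ,c,i,k}. Two identities are
enforced by tests: the stacked prediction equals candidates·w +
intercept to 1e-10, and genotype·collapsed-weights reproduces the
stacked score minus intercept to 1e-8 on held-out samples. In-sample
dominance of the stack over every single candidate holds empirically
with OLS among the base learners and is asserted on the test fixtures;
it is not a theorem of the NNLS meta-learner.

With many candidates and a small tuning cohort the ensemble can
overfit; a warning cites the ~1000–3000 tuning-sample guidance for
continuous traits.

## Data handling

- Summary statistics are harmonized to the LD reference's allele
  orientation: matching key is snp_id; reversed alleles flip the sign
  of r and the frequency; strand-ambiguous A/T and C/G SNPs are dropped
  by default (keep-able by flag); mismatching alleles are dropped; a
  count report (kept/flipped/dropped) is returned.
- Genotypes: PLINK 1 bed/bim/fam via a small built-in codec; missing
  dosages are mean-imputed per SNP before standardization;
  standardization uses the population (1/n) standard deviation;
  monomorphic SNPs become zero columns and are flagged.
- LD: Pearson correlation of mean-imputed dosages within BED-defined
  blocks (0-based half-open), computed on SNPs with reference
  MAF > 0.01. SNPs outside every block are assigned to the nearest
  block on their chromosome, with a logged count. Serialization is one
  dense matrix per block in an .npz container plus a JSON index with
  ids and a checksum.
- z-score inputs convert via r = z/√n clipped to ±0.999 (alternative
  r = z/√(n−1+z²) selectable).

## Synthetic data generator

The generator emulates the structure of a multi-ancestry PRS study at
desk scale. Defaults (chosen once, fixed):

| parameter | default | rationale |
|---|---|---|
| populations | EUR-like + target | two-population transfer setting |
| p_snps / block_size | 2000 / 100 | desk-scale stand-in for genome-wide SNP content |
| LD | AR(1), ρ = 0.9 / 0.7 | heterogeneous LD, EUR-like panel more structured |
| shared SNP fraction | 0.8 | HM3/MEGA-like cross-population overlap |
| p_causal | 0.01 | high-polygenicity scenario |
| h² | 0.4 | common-SNP heritability of the emulated studies |
| ρ_effect | 0.8 | cross-population causal-effect correlation |
| α | 0 | standardized scale = strong negative selection; exposed for milder regimes via per-SNP variance ∝ [2f(1−f)]^α |
| n_gwas | 100,000 / 15,000 | large auxiliary + small target GWAS |
| n_tune / n_valid | 10,000 / 10,000 | tuning and validation cohort sizes |

Causal SNPs are a Bernoulli(p_causal) subset; shared causal SNPs get
jointly normal effects with pairwise correlation ρ_effect; each
population's effect vector is rescaled so its genic variance βᵀRβ
equals h² exactly (so "realized heritability" is calibrated by
construction and verified empirically on simulated cohorts). Summary
statistics are drawn directly from the sampling distribution
r̂ ~ N(Rβ, R/n) per block via a symmetric matrix square root; an
individual-level GWAS mode exists and is used to cross-validate the
direct sampler's mean and covariance. Cohorts are drawn as N(0, R)
(standardized mode) or discretized to 0/1/2 through a two-haplotype
binomial-probit construction (dosage mode, used for PLINK output);
phenotypes are Xβ plus normal noise of variance 1 − h², with optional
covariates and a liability-threshold binary mode.

What the generator does **not** emulate: genome-scale SNP content
(2.5M), realistic haplotype/coalescent structure, admixture,
frequency-dependent selection regimes beyond the α exponent, and
population-specific LD block boundaries. Consequently, passing tests
demonstrate correctness of the algorithms and calibration of the
sampler — not real-data predictive performance.

A consequence of the desk-scale defaults worth stating explicitly:
with h² = 0.4 concentrated on ~20 causal SNPs, a 15,000-sample target
GWAS measures each causal effect at z ≈ 17, so a target-only lasso is
already at the heritability ceiling and cross-population borrowing has
nothing to add (the similarity penalty can only bias). The qualitative
transfer-learning gain appears when the target GWAS is underpowered at
the per-SNP level; the suite demonstrates it in a weak-target regime
(p = 1000, p_causal = 0.05, h² = 0.05, n_target = 2000), where the
joint ensemble roughly doubles validation R² over the target-only
lasso.

## Evaluation

- Continuous: squared Pearson correlation between the score and the
  covariate-residualized phenotype (plain R² with no covariates);
  affine-invariant; zero-variance scores give 0 with a warning.
- Binary: Mann–Whitney AUC with midrank ties. Covariate adjustment for
  AUC residualizes the *score* on the covariates — an approximation to
  a regression-adjusted AUC, flagged as such in the output metadata.
- Logit-scale variance from AUC: the default implements σ² = 2·Φ⁻¹(AUC)
  as printed in the source analyses; the liability-scale relation
  σ² = 2·(Φ⁻¹(AUC))² is available behind a `squared` flag, since the
  printed form and the standard derivation disagree and we do not
  adjudicate intent.
- Relative improvement: (a − b)/b.

## Known limitations

- The joint solver stores one dense R per population per block; fine at
  desk scale, wasteful for genome-scale panels (a shared-block sparse
  layout would be the next step).
- The NNLS meta-learner guarantees neither in-sample dominance nor
  out-of-sample superiority of the stack; with small tuning cohorts the
  non-ensembled best candidate can be more robust.
- Binary-trait support in the end-to-end pipeline is limited to the
  metrics and ensemble layers; the simulation study driver
  (`run_study`) is continuous-trait only.
- Adaptive-lasso and fused-lasso penalty variants, and
  allele-frequency-exponent generalizations of the model itself, are
  out of scope.
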