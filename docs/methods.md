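# Methods

`pleioprs` builds polygenic risk scores (PRS) for a target disease by
jointly modelling two genetically correlated diseases from their GWAS
summary statistics, optionally stratifying per-SNP heritability by
functional annotations. This note describes the statistical model, the
estimation algorithms, and the synthetic-study machinery, in the order the
pipeline executes them.

## 1. Data model and harmonization

All computations work on the standardized scale: genotypes and phenotypes
are treated as mean-zero, variance-one, so the marginal (single-SNP) GWAS
estimator for SNP *i* is

    beta_tilde_i = x_i' y / n,

with sampling variance approximately `1/n` under the null. Odds ratios are
converted via `log(OR)`; z-scores via `sign(z) |z| / sqrt(n)`.

Harmonization intersects the two traits' summary statistics, the reference
genotype panel, and the annotation table on SNP id; aligns effect alleles
to the panel (flipping the sign of `beta_tilde` when the effect allele is
the panel's other allele); and drops strand-ambiguous (A/T, C/G) variants
by default. The result is a single `HarmonizedStudy` in panel SNP order —
every downstream array is positionally aligned to it.

## 2. LD reference

LD is handled in two forms, both computed from the reference panel's
standardized genotypes:

- **Windowed blocks.** The genome is cut into blocks of at most
  `2 * ld_radius + 1` SNPs (never crossing a chromosome boundary); within a
  block the full local correlation matrix `D` is stored. Posterior
  computations treat blocks as independent.
- **Stratified LD scores.** For annotation category *c*,
  `l(i, c) = sum_{j in window(i), j in c} r_ij^2`, plus the unstratified
  total `l(i) = sum_j r_ij^2` over the same window. The total is a plain
  whole-genome LD score — categories are used only for the stratified
  regression, never double-counted into the total.

## 3. Annotation-stratified heritability

Per-category coefficients `tau_c` come from stratified LD-score regression:
for each trait, regress `n_i beta_tilde_i^2 - 1` on `n_i l(i, c)` across
categories `c`, with the intercept fixed at 1 (no confounding term; the
synthetic data have none) and weights `1 / max(l(i), 1)`.

The **total chip heritability** uses the method-of-moments inversion

    Hhat^2 = M (mean chi^2 - 1) / (mean n * mean l),

clipped to `[0.001, 0.9]`.

Per-SNP variances are assembled as `sigma2_i = sum_c tau_c 1[i in c]`,
floored at `Hhat^2 / (100 M)` (a SNP is never given exactly zero prior
variance), then rescaled so that `sum_i sigma2_i = Hhat^2` exactly. If the
raw assembly is non-positive everywhere, the prior falls back to uniform
`Hhat^2 / M`.

With a single whole-genome annotation this entire machinery reduces to the
uniform prior `sigma2_i = Hhat^2 / M`, which is how the non-annotated
model variants are implemented.

## 4. Infinitesimal joint posterior

Under the infinitesimal model every SNP is causal, with per-SNP bivariate
normal prior

    (beta_i, gamma_i) ~ N(0, [[sigma2_1i, rho sqrt(sigma2_1i sigma2_2i)],
                              [ .       , sigma2_2i               ]]),

where `rho` is the genetic correlation. Per block, the posterior mean of
the `2 M_b` stacked effects given `(beta_tilde, gamma_tilde)` is the
conjugate ridge-type solve

    (Sigma_prior^{-1} + K^{-1} kron D) m = (K^{-1} kron I) (beta_tilde; gamma_tilde),

with `K = [[1/n1, a], [a, 1/n2]]` and `a = N_s rho_e / (n1 n2)` encoding
sample overlap (`N_s` shared individuals, residual correlation `rho_e`).
At `rho = 0` and `a = 0` the system decouples exactly into two independent
single-trait solves — a property the test suite pins to 1e-10.

When `rho` is not supplied it is tuned over the grid
`(-0.9, -0.7, -0.5, -0.3, -0.1, 0, 0.1, 0.3, 0.5, 0.7, 0.9)` by split-half
validation accuracy on the validation cohort.

## 5. Non-infinitesimal joint posterior (Gibbs)

The sparse model assigns each SNP to one of four components — causal in
both traits (11), trait 1 only (10), trait 2 only (01), or neither (00) —
with proportions `p = (p11, p10, p01, p00) ~ Dirichlet(alpha)`. Given
membership, causal effects are independent normals with slab variances

    sigma2_1i / (p11 + p10)   and   sigma2_2i / (p11 + p01),

so each trait's expected per-SNP variance contribution stays `sigma2_ti`
regardless of sparsity.

One Gibbs sweep updates, per SNP within each block:

1. The residualized estimator `Delta_i = beta_tilde_i - sum_{j != i} D_ij beta_j`.
2. Component weights by the evidence ratio
   `slab/spike = (N sigma_slab + 1)^{-1/2} exp(N C Delta^2 / 2)` per trait,
   with shrinkage `C = N / (N + q / sigma2)` where `q` is the trait's
   causal mass (`p11 + p10` or `p11 + p01`).
3. A component draw, then the effect draw `N(C Delta, C / N)` if causal in
   that trait, exactly zero otherwise.

After each sweep, `p` is updated by Metropolis–Hastings with a
`Dirichlet(alpha + counts)` proposal. Because the slab variances depend on
`p`, the target adds `0.5 m_c log q - 0.5 q S` terms (over the causal
effects `S = sum beta_i^2 / sigma2_i`) and the proposal is not exactly
conditional; with `p_dependent_slabs=False` the extra terms vanish and the
acceptance probability is identically 1, which the tests pin.

**Mixing caveat.** In weak-identifiability regimes (small M, little
signal) the slab-variance terms can make the MH acceptance extremely small
and `p` effectively freezes at its initial value. The effect-vector chain
remains correct for that fixed `p`, and at realistic scales (thousands of
SNPs with real signal) acceptance is healthy (~0.75 in our checks) and `p`
adapts. Posterior effect means — not `p` concentration — are the
guaranteed outputs.

The posterior mean effect vector, averaged over retained sweeps, is the
PRS weight vector. A shrink factor clips each trait's implied heritability
per sweep to the LD-score estimate, stabilizing early iterations.

## 6. Model variants

Eight variants share this machinery:

| variant | traits | prior | sparsity |
|---|---|---|---|
| `ldpred-inf` | 1 | uniform | no |
| `annopred-inf` | 1 | annotation | no |
| `pleiopred-inf` | 2 | uniform | no |
| `pleiopred-anno-inf` | 2 | annotation | no |
| `ldpred` | 1 | uniform | yes |
| `annopred` | 1 | annotation | yes |
| `pleiopred` | 2 | uniform | yes |
| `pleiopred-anno` | 2 | annotation | yes |

Single-trait sparse variants use the degenerate two-component
(causal/null) sampler.

## 7. Scoring and evaluation

PRS = genotype matrix (standardized, float32) times posterior mean
effects, matched on SNP id with allele-flip sign correction; SNPs absent
from the weight table are skipped and counted. Evaluation reports Pearson
correlation for quantitative phenotypes and AUC for binary ones, plus a
likelihood-ratio test comparing two PRS in a joint logistic model and
top-quantile case enrichment. Hyper-parameters (e.g. the `rho` grid) are
tuned by split-half accuracy on the validation cohort: fit direction on
one half, evaluate on the other, average the two folds, pick the best
(ties to the lowest grid index).

## 8. Synthetic studies

The generator produces two training cohorts, a test cohort, annotations,
true effects and summary statistics from a single seed. Problem sizes are
the package's own desk-scale choices — large enough to exercise every code
path, small enough to run on one CPU core:

- `M = 5,000` SNPs (default), one chromosome, MAF ~ Uniform(0.05, 0.5).
- LD: `independent` (binomial HWE draws) or `autoregressive`, which
  emulates local LD by building each haplotype as a copy chain — adjacent
  SNPs hit a target correlation `rho_adj` and correlation decays
  geometrically with distance.
- Two annotations, each covering 10% of SNPs; causal SNPs are allocated
  over the disjoint strata A1, A2 \ A1, complement proportionally, so
  annotation enrichment is real and known.
- A fraction `shared_prop` of causal SNPs is shared between the traits
  (optionally with identical effect values); per-trait effects are scaled
  so the genetic variance is exactly `h2`.
- Summary statistics are exact marginal estimators `X'y / n` on the
  standardized training data; optional sample overlap with residual
  correlation `rho_e` induces the expected `N_s rho_e / n` estimator-noise
  correlation. Binary traits threshold the liability at the target
  prevalence.

## 9. Numerical choices and limitations

- Genotype standardization and PRS accumulation use float32 (memory), all
  posterior algebra float64.
- Block posteriors use Cholesky solves; no matrix is ever explicitly
  inverted in the per-block hot path.
- Determinism: every stochastic routine takes a seed; a pipeline rerun
  with the same seed is bitwise identical.
- At desk scale (M = 5,000) the *annotation increment on top of joint
  modelling* is within Monte-Carlo noise: the 3-category tau estimates are
  noisy enough that the annotated prior injects about as much noise as
  signal. The joint-modelling gain over single-trait models is robustly
  visible; the full annotation benefit requires much larger M.
- The MH mixing caveat of section 5 means `p` trajectories should not be
  interpreted on small systems.
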