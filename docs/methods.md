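# Methods

`polyhet` estimates how much of the genetic architecture two clinically
defined disease subtypes share. The pipeline mirrors the standard
statistical-genetics workflow for this question: quality-controlled
genotypes feed a genetic relationship matrix (GRM), restricted maximum
likelihood (REML) on that matrix yields per-subtype SNP heritability and a
bivariate genetic correlation, and a permutation contrast distinguishes
"subtypes genuinely differ" from "any random split of a complex disease
looks different". All of it is exercised on a synthetic liability-threshold
cohort generator, so every claim the test suite makes is about recovery of
known truth.

## Generative model

Each individual carries `m` unlinked biallelic SNPs with allele
frequencies drawn uniformly from a configurable MAF range and genotypes in
Hardy–Weinberg proportions. A subset of `n_causal` SNPs receives effect
pairs `(beta_1, beta_2)` drawn from a bivariate normal with correlation
`rho_effects`, rescaled so that the genetic variance of each standardized
liability equals the target `h2_liab_k` exactly. Liabilities are
`g_k + e_k` with independent Gaussian environments; an individual is a
subtype-`k` case when liability `k` exceeds `Phi^{-1}(1 - K_k)`.

Defaults encode the study conditions the package targets: lifetime
prevalences `K_1 = 0.006` and `K_2 = 0.004`, liability heritabilities
0.35 and 0.25, effect correlation 0.78, ascertained case groups of
2811 / 1398 with 11 164 shared controls over four collection sites.
Desk-scale analyses pass smaller explicit targets; the defaults document
the reference design rather than a convenient test size.

Deliberate simplifications: genotypes are unlinked by default (REML and
genetic-correlation properties do not require LD; an autoregressive
haplotype-block mode exists solely to exercise LD pruning and index-SNP
selection); population structure is limited to an optional two-population
Balding–Nichols frequency divergence for MDS testing; individuals crossing
both liability thresholds receive the subtype with the larger threshold
exceedance, making subtypes mutually exclusive diagnoses; liabilities are
standardized with the generative allele frequencies so truth values are
exact. Consequently, passing tests demonstrate correctness of the
estimators under the model's own assumptions — they do not probe LD-induced
biases, batch artifacts or fine-grained stratification in real data.

## Quality control

The QC ladder applies, in order: SNP missingness > 5%; individual
heterozygosity > 15% and individual missingness > 2%; SNP missingness
> 2%; MAF < 1%; Hardy–Weinberg exact test P < 5e-5; case/control
differential missingness P < 1e-3. Choices the contract left open:

- HWE is computed in controls only (standard case-control practice, so
  true associations are not removed as HWE failures).
- Differential missingness uses a 2x2 chi-square on called/missing by
  case/control without continuity correction.
- The heterozygosity rule is an *absolute* rate, as specified. On a
  simulated common-SNP panel (MAF 5–50%) the expected heterozygosity is
  ~30%, so the default would remove everyone; this is a property of the
  rule, not a bug. Analyses of such panels should raise `indiv_het_max`
  (tests do); the default documents the array-data convention where
  genome-wide heterozygosity is far lower.
- The HWE exact test follows the conditional enumeration over heterozygote
  counts with a numerically stable recurrence; it is validated against a
  direct log-gamma enumeration to 1e-12 up to n = 200.

LD pruning slides a window of 100 SNPs by 50 and removes the SNP with the
highest variance inflation factor (`1/(1-R^2)` against the other retained
window SNPs) until all VIF <= 2; ties drop the later SNP, so the procedure
is deterministic. Ancestry structure is summarized by classical MDS on
1 - IBS distances; an individual is an ancestry outlier when any of the
top ten components puts it more than `k_sd = 6` standard deviations from
the component mean (a concretization chosen so that a homogeneous cohort
is flagged with probability < 1e-6 per individual per component under
normality, while Balding–Nichols outliers at Fst 0.3 are flagged reliably).
Relatedness uses PLINK-style method-of-moments IBD from IBS counts and
sample allele frequencies without the small-sample correction terms
(pairwise errors stay within the +-0.05 the tests require at 10 000 SNPs);
PIHAT = P(IBD=2) + P(IBD=1)/2, flagged above 0.1, removing the member of
each pair with higher missingness.

## GRM and REML

The GRM is the allele-frequency-standardized cross-product
`A_jk = mean_i z_ij z_ik` over SNPs non-missing in both individuals, with
sample frequencies from the combined analysis cohort. The diagonal uses
the same standardized formula as the off-diagonals; a `gcta` dialect flag
provides the alternative diagonal estimator. The vectorized computation is
tested against an explicit double loop at 1e-10.

Univariate REML fits `y = Xb + g + e`, `V = sg2 A + se2 I`, by one EM step
followed by average-information (AI) updates with step-halving, variance
components floored at `1e-8 x Var(y)`, convergence at `|delta loglik| <
1e-6` within 100 iterations. The fit rotates into the eigenbasis of `A`,
making each iteration O(n p^2) and allowing the eigendecomposition to be
amortised across repeated fits on one GRM. Standard errors come from the
inverse AI matrix; `h2 = sg2/(sg2+se2)` and its SE by the delta method.
When no AI step can improve the likelihood, a guaranteed-ascent EM step is
attempted; if that also fails to improve beyond tolerance the point is a
numerical optimum (possibly on the constraint boundary) and is reported as
converged.

The bivariate model stacks two traits measured on *disjoint* individual
sets: `V = [[g1 A11 + e1 I, g12 A12], [g12 A21, g2 A22 + e2 I]]` with
residual covariance structurally zero. The genetic correlation is
`rg = g12 / sqrt(g1 g2)`, constrained to [-1, 1] by bounding
`|g12| <= sqrt(g1 g2)`; its SE is by the delta method on the (g1, g12, g2)
block of the inverse AI matrix. Projected AI updates can stall on the
constraint boundary for small noisy problems, so fits with stacked size
<= 500 are refined by a Nelder–Mead pass on a bounded reparametrisation
(log variances, `g12 = tanh(t) sqrt(g1 g2)`); the refined optimum is kept
only when it strictly improves the restricted likelihood. Tiny-instance
equivalence with independent grid searches of the likelihood surface is
part of the acceptance suite.

Case-control traits are fit on the observed 0/1 scale and transformed to
the liability scale by `h2_liab = h2_obs K^2 (1-K)^2 / (P(1-P) z^2)`, with
`K` the population prevalence, `P` the ascertained case proportion and `z`
the standard-normal density at the liability threshold. Two independent
subtype estimates are compared with a normal z-test on the difference
(the degrees of freedom a t-reference would need are unavailable; with
cohort-scale estimates the distinction is negligible).

## The subtype-contrast permutation design

Comparing two case groups against a *shared* control group inflates rg, so
the control pool is split into two even, non-overlapping halves, one per
trait. One hundred control permutations give 100 subtype-pair rg
estimates; for each control split the pooled cases are re-split 100 times
into random groups of the same sizes, giving 10 000 mixed-pair estimates.
If subtypes share one architecture the two distributions coincide; under
genuine heterogeneity the subtype-pair distribution sits lower, tested
with a Welch (unequal-variance) two-sample t on converged estimates —
non-converged fits are excluded but always counted and reported. A balance
gate first excludes any subtype with more than 75% of its cases from a
single site, and flags sites whose contributions to the two subtypes are
grossly imbalanced (ratio above a configurable 3:1 — the gate's second rule
needed a number and none is canonical).

Because rg is constrained to [-1, 1] and mixed pairs sit near 1, the
mixed-pair mean is biased slightly below 1 while the subtype-pair mean
tracks `rho_effects` with mild downward attenuation from GRM sampling
noise at desk-scale SNP counts; the contrast ordering is unaffected and no
analytical boundary-bias correction is applied.

Desk-scale defaults run the design at 10 control permutations x 10 case
splits (110 bivariate fits at a stacked size near 1200), sized so the
whole contrast runs in minutes on one core; the full 100 x 100 design is a
configuration value, and the plan generator is validated at that scale
(exactly 100 + 10 000 plans with disjoint, exhaustive, evenly sized
control halves).

## Association, meta-analysis, replication tests

The association scan is per-SNP logistic regression of status on allele
dosage (hard calls or expected dosages in [0, 2]; missing calls
mean-imputed) plus shared covariates, with Wald statistics — implemented
as a Newton/IRLS solver vectorized across SNPs and verified against
statsmodels per-SNP fits to 1e-6. Monomorphic or separated SNPs yield NA
rows with reason codes. Ancestry covariates are the top-10 MDS components
individually associated with phenotype at alpha = 0.05.

Meta-analysis is inverse-variance fixed effects with Cochran's Q
(chi-square, k-1 df). Studies are aligned to the first study's effect
alleles; swapped codings flip the effect sign, and strand-ambiguous A/T
and C/G SNPs are dropped at every alignment boundary (meta, sign test,
scoring), since strand cannot be resolved without frequency heuristics.
The genomic inflation factor is the median association chi-square over
0.4549. Index SNPs are selected greedily (most significant remaining SNP;
drop neighbours within 500 kb at r^2 > 0.1 in a reference panel — both
values are exposed flags, as "approximate linkage equilibrium" is not
otherwise pinned down). Sign-test concordance of aligned effect directions
is tested against 0.5 with a two-sided exact binomial at discovery
thresholds {1e-3, 1e-4, 1e-5, 1e-6}; genome-wide-significant SNPs
(P < 5e-8) merge into regions within 250 kb.

## Polygenic scoring

Scores are sums of effect-allele dosages weighted by discovery log-odds
over SNPs below each threshold in the grid {0.001, 0.01, 0.05, 0.1, 0.2,
0.5, 1.0} (a `unit` mode counts risk alleles instead); missing dosages are
imputed as twice the allele frequency. Discrimination is reported as the
t-statistic of the score coefficient in a logistic model with covariates,
and as Nagelkerke's delta-R^2 — the pseudo-R^2 of covariates plus score
minus that of covariates alone, both normalized by the intercept-only
model. Case-case contrasts regress subtype membership on the score; the
reported direction names the higher-scoring group.

## Numerical and testing notes

- All randomness flows from explicit seeds; each generator stage draws
  from its own `SeedSequence` child, so a configuration fully determines
  every output and stages can be re-run independently.
- REML restricted log-likelihoods omit the `n log(2 pi)` constant; grid
  and simplex cross-checks in the tests use the same convention via an
  independent `slogdet`-based evaluation.
- Simulation scales in the test suite (for example 2000 individuals x
  5000 SNPs with 20 replicates for heritability recovery, a 10 x 10
  contrast design near stacked size 1200, and 30 000–50 000 SNP null
  scans) are chosen as the smallest designs at which the Monte-Carlo
  error bounds in the assertions are meaningful on a single core.
- Text formats round floats to 6 significant digits except the GRM, which
  is written at full precision and parsed with round-trip float precision.

## Known limitations

- Observed-scale GREML on strongly ascertained case-control cohorts,
  followed by the K/P liability transform, is known to underestimate
  liability heritability: the transform corrects the scale but not the
  full effect of ascertainment on the relationship between GRM and
  phenotype. At the default design (K near 0.5%, cohort case fractions
  near 30%) the recovered liability h2 sits some 20-30% below the
  generative truth, as the acceptance script's numbers show. This bias is
  a property of the estimator family the package implements;
  ascertainment-robust alternatives (PCGC-style Haseman-Elston
  regression) are out of scope. Observed-scale recovery on
  non-ascertained phenotypes is unbiased (and tested). The subtype-pair
  vs mixed-pair rg *contrast* is unaffected in its ordering, since both
  arms share the same design.
- No LD-aware heritability models (LDSC/LDAK-style), no GxE, no sparse or
  very-large-n optimizations; dense REML is practical to a few thousand
  individuals per fit.
- The PLINK-style IBD moments omit the finite-sample allele-frequency
  corrections; PIHAT on very small cohorts is biased accordingly.
- The liability transform assumes single-stage ascertainment and a normal
  liability; site effects enter REML only as optional covariates.
- Imputation itself is out of scope: imputation-quality scores are
  consumed (info > 0.3 filter), never produced.
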