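# Methods

## Model and tests

Each participating study contributes per-sex per-variant summary
statistics from an additive linear model of a quantitative trait on
allele dosage: an effect estimate β̂ (trait units per effect allele), its
standard error, effect-allele frequency and sample size.  Under
Hardy–Weinberg genotype frequencies and a unit-variance residual, the
sampling variance of β̂ is 1/(2Nf(1−f)) for N individuals and allele
frequency f; this closed form is used throughout (generator, power
oracle, conditional analysis).

Study estimates are pooled per sex by fixed-effects inverse-variance
weighting: β̂ = Σwᵢβ̂ᵢ/Σwᵢ, SE = (Σwᵢ)^(−1/2), wᵢ = 1/SEᵢ².  Three
association tests are derived from the pooled per-sex pair:

- sex-combined (1 df): IVW of the two sexes, z² against χ²₁;
- sex-dimorphic (2 df): T² = z_f² + z_m², against χ²₂
  (p = exp(−T²/2) in closed form, asserted against the generic survival
  function to 1e-12);
- sex-heterogeneity: Cochran's Q = Σwᵢ(β̂ᵢ−β̂)², which for two groups
  reduces to (β̂_f−β̂_m)²/(SE_f²+SE_m²), against χ²₁, with
  I² = max(0,(Q−df)/Q)·100.

These satisfy the exact algebraic identity z_f² + z_m² = z_pooled² + Q,
which the suite checks to 1e-10 on 10⁵ random pairs: the 2-df statistic
is the association chi-square plus the heterogeneity chi-square.

**Genomic control.** λ = median(χ²)/0.45494 (the χ²₁ median).  When
λ > 1, standard errors are inflated by √λ; λ < 1 is left uncorrected —
GC is a guard against residual confounding, not a variance estimator,
and deflating would anti-conservatively sharpen every test.  GC is
applied per study before pooling and, configurably (default on), a
second time to the pooled per-sex statistics.  For Metabochip-style
designs the median can be restricted to a designated null-SNP subset,
since the array's SNP content is enriched for true associations.

**Missing sexes.** A variant absent in one sex still receives a
sex-combined estimate; the dimorphic and heterogeneity columns are set
to NaN rather than silently degrading to a 1-df test.

## Locus discovery and conditional analysis

A lead must reach P ≤ 5e-8 in the 2-df dimorphic or 1-df combined test.
Lead selection is greedy per ±500 kb window: lowest relevant p wins,
ties broken by position (the tie-break is our choice; any deterministic
rule works because the call set is asserted invariant to input row
order).  A lead is novel when it lies > 500 kb from every known lead for
the trait and has r² < 0.01 with all of them; LD comes from a
user-supplied pairwise table, and without one the distance rule decides
alone.  Heterogeneity at established loci is screened at 0.05/36 (FG)
and 0.05/19 (FI).

The two-SNP conditional analysis reconstructs the joint least-squares
fit from marginal summaries: with genotype variances vⱼ = 2fⱼ(1−fⱼ) and
covariance r√(v₁v₂), the joint coefficients solve V b = (v₁β̂₁, v₂β̂₂).
The phenotypic variance is recovered from each marginal fit
(var_y ≈ n·v·SE² + v·β̂²) and prices the conditional SE via the joint
residual variance.  |r| ≥ 0.99 raises a singularity error; r = 0 returns
the marginal estimate verbatim (orthogonal predictors leave the fit
untouched, and the reconstruction's residual-variance estimate would
otherwise differ from the marginal SE by a cosmetic O(vβ²) term).  The
oracle is individual-level joint OLS on simulated genotype pairs
(Gaussian-copula haplotypes, n = 2,000), agreement within 2 joint SEs on
≥ 95% of ~200 replicates across r ∈ {0, 0.3, 0.6} × CAF ∈ {0.1, 0.3, 0.5}.

## Power study

Three sex-effect scenarios: homogeneous (β_m = β_f), dimorphic
(β_m fixed at 0.05 SD units, β_f varied) and single-sex (β_m = 0).
Reference conditions: 70,000 per sex, 10,000 replicates per setting,
CAF ∈ [0.05, 0.5], β ∈ [0, 0.1] SD units, α = 5e-8 for the main grids
and the Bonferroni levels 0.05/36, 0.05/19 for the established-locus
heterogeneity screen.  The default simulation samples β̂ per sex directly
from Normal(β, SE²) — valid because the per-sex least-squares estimate
is asymptotically normal with the closed-form SE; a genotype-level mode
(Binomial(2,f) genotypes, unit-residual trait, per-sex OLS) is retained
as the fidelity oracle and cross-validated at N = 5,000.  The residual
variance is taken as 1: a single SNP at β ≤ 0.1 explains ≤ 0.5% of a
unit-variance trait, so the approximation errs by under half a percent
on SEs.  Analytic power is the noncentral-χ² survival beyond the central
α-quantile with ncp = (β/SE)² (combined/female), ncp_f + ncp_m
(dimorphic, 2 df), or (β_f−β_m)²/(SE_f²+SE_m²) (heterogeneity).
Critical values are always derived from α, never hard-coded.

## Mendelian randomization

Per-variant causal estimates are Wald ratios β_out/β_exp with
first-order Delta SEs (SE_out/|β_exp|; the second-order exposure term is
available by flag — the first order matches common two-sample practice
where instruments are strong).  The combined estimate is the weighted
zero-intercept regression of outcome on exposure effects with weights
1/SE_out² — algebraically the fixed-effects IVW of the ratios — with the
SE inflated multiplicatively by √max(1, Q/(k−1)) (random-effect
behavior, floored so homogeneous sets reproduce fixed effects exactly).
MR-Egger adds a free intercept after orienting all instruments to
β_exp ≥ 0; its intercept estimates directional pleiotropy and its slope
stays consistent under it.  Egger inference uses a t reference with
k − 2 df and overdispersion floored at 1.  Instruments are selected at
P ≤ 5e-8 with greedy r² < 0.001 pruning (1-Mb distance fallback,
flagged).  The bidirectional orchestration runs both directions in both
sexes and judges the four IVW tests at 0.05/4 = 0.0125.

The reference-scale causal estimate (slope 1.86 at k = 222 instruments)
is exercised as parameter recovery on synthetic instrument sets, not as
a data reproduction: the original instrument tables are consortium
artifacts that the package does not bundle.

## Expression models

Per gene, two nested linear fits with sex means, plate effects and a
genotype slope: common slope versus sex-specific slopes.  The
sex-interaction test is the 1-df contrast β_f − β_m from the joint fit;
it coincides with the nested-model F statistic (t² = F for a
one-parameter comparison), asserted within 2%.  Because the design is
shared across genes, all fits are vectorized through one pseudoinverse.
Sex-differential expression regresses (probe-averaged) expression on a
female indicator plus covariates — positive effects mean higher
expression in women.  Random plate/family effects of the original
mixed-model analyses are approximated by fixed plate effects; this
widens no SE in the balanced synthetic designs used here and is a
documented simplification.  Multiple testing uses Benjamini–Hochberg
step-up FDR (delegated to statsmodels); label-permutation p-values
(default 10,000 permutations, seeded) are optional.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses assume:
normally distributed effect estimates with the closed-form SE, shared
allele frequencies across studies, configurable sex-specific true
effects, per-study sampling-variance inflation λ (reported SEs stay
nominal, so the inflation is visible to GC exactly as residual
stratification would be), and allele-coding discordance (swaps and
strand complements in equal proportion; palindromic pairs only on
request, to exercise the rejection path).  Phenotype preparation applies
the whole-blood-to-plasma factor 1.13 to FG, excludes diabetes-flagged
individuals and plasma FG ≥ 7 mmol/L, and log-transforms FI.

It does **not** simulate LD between variants (beyond the block
structures used for pruning tests), between-study effect heterogeneity,
allele-frequency drift across studies, imputation error, or relatedness
— so passing tests demonstrate correctness of the estimators under
their stated sampling model, not robustness to those real-data
violations.  Every generator requires a seed and writes a truth table;
recovery tests read truth only from there.

## Numerical and statistical testing choices

- P-values are floored at 1e-300; the chi-square statistic is always
  reported alongside, so no information is lost to underflow.
- QC rules are strict inequalities; values exactly at a threshold
  survive.  Absent optional QC fields never cause removal.  Removed rows
  are attributed to the first failing rule in a fixed order so report
  counts sum exactly; the surviving set is order-independent.
- Palindromic harmonization requires both frequencies to sit more than
  0.08 from 0.5; otherwise the record is rejected with a dedicated
  reason code rather than guessed.
- Stochastic calibration tests use explicit error budgets: empirical
  rates within 3 binomial SEs of nominal, empirical-vs-analytic power
  within 4 Monte-Carlo SEs.  Coverage checks of "within 2 SE" recovery
  (nominal probability ≈ 95.4%) are asserted with a 3-binomial-SE
  one-sided allowance below 95%, since a point estimate from a few
  hundred seeds fluctuates by ±1.5% even for a perfectly calibrated
  estimator.
- Problem sizes in the scripted analyses (5,000-variant cohort, 10,000
  power replicates, 200-seed recovery loops, n = 2,000 conditional
  oracles) were chosen so each Monte-Carlo error budget is a small
  fraction of the effect being measured.

## Known limitations

- The meta-analysis is fixed-effects across studies by design;
  between-study random effects are out of scope.
- Only the two-SNP conditional analysis is provided, not stepwise
  multi-SNP model selection.
- Chromosome X is not handled; coordinates are GRCh37 autosomes.
- The fixed-effects approximation to the expression mixed models is
  exact only when clusters are balanced with respect to sex.
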