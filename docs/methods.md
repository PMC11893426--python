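# Methods

This note documents the statistical models implemented in `mrpipe`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Instrumental-variable model

A SNP is a valid instrument for exposure X on outcome Y when it is
(i) associated with X (relevance), (ii) independent of confounders, and
(iii) affects Y only through X (exclusion / no horizontal pleiotropy).
`mrpipe` works entirely with two-sample summary statistics: per-SNP effect
β̂ₓⱼ (SE σₓⱼ) from the exposure GWAS and β̂ᵧⱼ (SE σᵧⱼ) from the outcome
GWAS, aligned to the same effect allele.

### Instrument selection (`instruments`)

- p-value screen: keep SNPs with exposure p < `p_instrument`
  (default 1 × 10⁻⁵, the conventional threshold for molecular traits where
  5 × 10⁻⁸ leaves too few instruments).
- LD clumping: greedy by ascending p (ties broken by SNP id for
  determinism); a kept SNP removes all others on the same chromosome
  within `window_kb` (default 10,000 kb) with r² > `r2_max`
  (default 0.001). The LD matrix is a user input (or synthetic); the
  package does not ship or download a reference panel.
- Strength: per-SNP F = (β̂ₓ/σₓ)², the squared Wald Z — the standard
  two-sample approximation. The default filter keeps F ≥ 10 per SNP; the
  mean F across candidates is also reported, since strength rules are
  quoted either way in the literature.
- Proxies: when an instrument is missing from the outcome GWAS, the best
  outcome-side SNP with r² > 0.8 may substitute (off by default).

### Harmonization (`harmonize`)

The outcome record is rewritten to refer to the exposure's effect allele:
label swaps flip the outcome beta's sign and complement its frequency;
strand-complement labels are complemented first (attempted only when
direct and swapped matching both fail). Palindromic SNPs (A/T, C/G) carry
no strand information in their labels, so allele frequency arbitrates:
when either side's EAF lies within `eaf_window` (default 0.08) of 0.5 the
SNP is dropped as unresolvable; otherwise orientation follows the minor
allele side of 0.5. A palindromic SNP missing EAF on either side is
dropped. The window and a `keep_palindromes` escape hatch are config
options for sensitivity reruns. The `action` field records one code per
record; a strand correction that also entails a label swap is recorded as
`strand_flipped` (the sign flip is visible in the stored beta).

Harmonization never modifies the exposure side, and for non-palindromic
SNPs it is an exact inverse of any combination of allele swap and strand
relabeling — a property the test suite asserts exactly, not approximately.

### Estimators (`estimators`)

- IVW: weighted regression of β̂ᵧ on β̂ₓ through the origin, weights 1/σᵧ²;
  algebraically the inverse-variance-weighted mean of Wald ratios with
  weights β̂ₓ²/σᵧ². Fixed-effects SE is 1/√Σ(β̂ₓ²/σᵧ²). The default is the
  multiplicative random-effects model, which inflates the SE by
  max(1, √(Q/(n−1))): it leaves homogeneous sets untouched and widens
  intervals under heterogeneity without discarding the estimate, matching
  the practice of reporting IVW alongside a significant Q. A single SNP
  degenerates to the Wald ratio with a warning-level method label.
- Cochran's Q uses first-order ratio weights β̂ₓ²/σᵧ², df = n − 1.
- MR-Egger: effects are first oriented so all β̂ₓ ≥ 0 (pairwise sign
  flips; estimates are invariant to this representation), then weighted
  least squares with intercept. Both SEs carry the overdispersion scale
  max(1, √(RSS_w/(n−2))). The intercept estimates average directional
  pleiotropy; its Wald test is the pleiotropy diagnostic.
- Weighted median: ratios ordered, inverse-variance weights normalized;
  the estimate interpolates the weighted empirical CDF at 0.5 using the
  midpoint convention (equal weights and odd n reproduce the sample
  median exactly). SE by parametric bootstrap: β̂ₓ*, β̂ᵧ* drawn from their
  sampling normals, 1000 replicates, seeded.
- Weighted mode: Gaussian-kernel weighted density of the ratios with
  bandwidth `bandwidth_factor` × 0.9·min(sd, 1.4826·MAD)·n^(−1/5) (the
  modified Silverman rule); the estimate is the density argmax on a
  512-point grid spanning the ratios ±3 bandwidths; bootstrap SE as
  above. Forward screens report the weighted median, reverse screens the
  weighted mode.
- Leave-one-out: random-effects IVW per exclusion; an exclusion is
  flagged when it flips the estimate's sign or moves its p-value across
  0.05.
- Reporting: odds ratios exponentiate log-odds effects with the exact
  normal quantile (1.959964 at 95%), rounded to 4 decimals only at the
  report boundary.
- Multiple testing: Benjamini–Hochberg step-up across the exposure panel
  (one family per outcome screen, never pooled across outcomes). Tiers:
  *significant* if adjusted p < 0.05, *potential* if raw p < 0.05 but
  adjusted p ≥ 0.05, otherwise null.

### MR-PRESSO (`presso`)

For each SNP j the leave-one-out IVW slope θ̂₋ⱼ gives a residual
rⱼ = β̂ᵧⱼ − θ̂₋ⱼ β̂ₓⱼ; the observed weighted RSS is compared with K
simulated datasets drawn under the no-pleiotropy model
β̂ᵧⱼ* ~ N(θ̂₋ⱼ β̂ₓⱼ, σᵧⱼ), β̂ₓⱼ* ~ N(β̂ₓⱼ, σₓⱼ). All p-values use an
add-one correction, bounding them in [1/(K+1), 1]. Defaults: K = 1000;
per-SNP outlier flags at the Bonferroni threshold 0.05/n; the distortion
p-value compares the flagged-set distortion of the IVW estimate against
random same-size SNP subsets. The pipeline reports both raw and
outlier-corrected estimates and never silently drops SNPs. No attempt is
made to reproduce any particular MR-PRESSO software release's
random-number stream — agreement is distributional, verified by
calibration and power simulations.

### Two-step mediation (`mediation`)

Step 1 estimates a = effect of exposure on mediator with the exposure's
instruments; step 2 estimates b = effect of mediator on outcome with the
mediator's instruments. Candidates must be nominally significant
(p < 0.05) in both steps. The mediator's step-2 instrument set excludes
SNPs that instrument the exposure: such SNPs associate with the mediator
only through the exposure, and using them would route the exposure's
direct outcome effect into b̂ (in simulation this inflates the estimated
mediated proportion by half or more; with the exclusion the truth is
recovered to Monte-Carlo precision).

The indirect effect is a·b with the exact variance of a product of
independent normals,

    se(a·b) = √(a²σ_b² + b²σ_a² + σ_a²σ_b²),

i.e. the delta method *including* the second-order cross term. The cross
term matters at these effect sizes: the reference table's printed SEs are
reproduced only with it (first-order gives 0.0104 instead of 0.0109 for
the androstenediol row). The mediation proportion is 100·a·b/total with a
CI obtained by scaling the indirect effect's Wald CI by the total effect,
treating the total as fixed — this reproduces every printed bound in the
reference table but understates uncertainty by ignoring the total
effect's SE; a documented limitation. An indirect effect whose sign
opposes the total effect is labeled a suppression, which reproduces the
reference table's three suppressing rows exactly.

### PheWAS enrichment (`phewas`)

Each hit SNP is matched to 4 control SNPs (seeded uniform sampling
without replacement, controls never reused) on: minor allele frequency
within ±0.05 — read as absolute, since a relative ±5% of a rare allele
would leave near-empty match sets — and gene density, distance to nearest
gene, and LD-partner count (r² ≥ 0.50) each within ±50% relative. Match
shortfalls are logged, not fatal. Per trait, the count of nominally
associated SNPs (p < 0.01) among hits vs controls forms a 2×2 table
tested with a two-sided Fisher's exact test (point-probability method);
p-values are BH-adjusted across traits. Tables with a degenerate margin
report an undefined (NA) odds ratio with p = 1. No external trait
database is queried; the association table is an input.

## Synthetic data (`simulate`)

The generator emulates the summary-statistic structure the estimators
assume, under the study conditions the pipeline was designed around:
exposure GWAS n = 14,824 (a 91-protein Olink panel), outcome GWAS
n = 73,479 (FinnGen male infertility), mediator GWAS n = 8,299 (plasma
metabolites); 50 SNPs per instrument set; MAF ~ Uniform(0.05, 0.5);
true instrument effects ~ N(0, 0.05²) resampled until per-SNP F ≥ 10.

Per-SNP standard errors follow the standardized-trait approximation
1/√(2·n·maf(1−maf)) for continuous and binary traits alike; the
case-control refinement is deliberately out of scope, but
`effective_n_binary(cases, controls)` = 4/(1/n₁+1/n₀) lets scenarios
emulate unbalanced binary outcomes (680 cases / 72,799 controls behaves
like n ≈ 2,700, which is what keeps exposure instruments from leaking
into reverse-direction instrument selection, as in the real design).

Pleiotropy models: `balanced` adds mean-zero direct effects to a
`prop_pleiotropic` share of SNPs; `directional` mean-shifts them;
`inside_violating` correlates them with instrument strength at ρ = 0.5 to
demonstrate where MR-Egger fails. The mediation generator builds three
coherent GWAS under X→M→Y with total = direct + a·b by construction, and
can instead place the mediator downstream of the outcome to exercise the
reverse-direction screen. All generators are pure functions of
(scenario, seed); identical seeds give byte-identical tables.

What the generator does **not** emulate: LD between instruments (SNPs are
independent; the block LD matrices used in clumping tests are synthetic),
sample overlap between GWAS, allele-frequency differences between
cohorts, population stratification, and binary-trait liability-scale
effects. Passing tests therefore validate the estimators and pipeline
logic under their stated assumptions, not robustness to those real-data
complications.

### Known small-sample property: attenuation

Because observed exposure effects carry noise, IVW is attenuated by
roughly a factor F̄/(1+F̄) (weak-instrument regression dilution), and
selecting instruments on observed significance adds winner's curse. At
the study-scale exposure n (≈15k) with the default effect distribution
this is a few percent — visible in the README example (0.265 vs a true
0.3). Estimator-validation scenarios (CI coverage, mediation-proportion
recovery) therefore use larger GWAS (n = 500,000) where instrument
strength makes the attenuation negligible relative to Monte-Carlo error;
calibration under the null is unaffected by instrument strength and is
tested at the study-scale sizes.

## Numerical conventions and problem sizes

- p-values of exactly 0 are floored to 1 × 10⁻³⁰⁰ on read; parsed rows
  violating any record invariant are dropped with exactly one logged
  reason code, never coerced.
- Report tables are TSV with 17-significant-digit floats, so a
  write→read round trip is the identity on numeric fields.
- All randomness in a pipeline run derives from one root seed via named
  substreams keyed by stage and exposure name, so results are independent
  of panel ordering and exposure subsets.
- Simulation-based test sizes: 200 replicates for null calibration,
  300 for CI coverage and mediation recovery, 100 for MR-PRESSO power
  (K = 600 in that loop; K = 1000 elsewhere), 1,000-SNP fixtures for the
  harmonization involution. These sizes give Monte-Carlo standard errors
  comfortably below the margins being asserted while keeping the default
  test run fast.

## Deliberate non-goals

Multivariable MR, Steiger directionality filtering (the pipeline uses
bidirectional reruns instead), CAUSE/contamination-mixture estimators,
GWAS-VCF/tabix IO, liftover, computing LD from genotypes, and any live
web-service integration (trait databases, PPI networks, gene-set or
drug-signature enrichment services) are out of scope; the generic Fisher
enrichment in `phewas` is the only enrichment computation implemented.
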