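# Methods

This note records the modelling assumptions behind mrpipe, the defaults that
matter, the numerical choices, and what the synthetic-data tests do and do
not establish about real data.

## Two-sample summary-data MR model

All estimators operate on per-variant association summaries only. For an
instrument j the exposure association is β̂X,j ~ N(bj, σ²X,j) and the outcome
association β̂Y,j ~ N(θ·bj + αj, σ²Y,j), where θ is the causal effect of one
SD of exposure on the outcome (log-odds for binary outcomes) and αj is a
direct (horizontally pleiotropic) effect, zero for valid instruments. The
three core identifying assumptions are the usual ones: instruments are
associated with the exposure, independent of confounders, and affect the
outcome only through the exposure. The estimator battery spans the standard
robustness trade-offs: IVW is efficient but assumes all instruments valid;
Egger allows directional pleiotropy under InSIDE (αj independent of bj); the
weighted median tolerates up to half the weight on invalid instruments; the
mode estimators assume only that the largest cluster of ratio estimates is
valid (ZEMPA).

Positions are 1-based and inclusive throughout. Alleles are upper-cased on
read; only single-nucleotide A/C/G/T alleles are accepted. p = 0 on input is
clamped to 1e-300 with a warning rather than rejected.

## Instrument selection defaults

| parameter | default | rationale |
|---|---|---|
| significance threshold | p < 1×10⁻⁵ (strict <) | locus-wide significance, the convention for microbiome/metabolite exposures where genome-wide hits are scarce |
| clumping | r² < 0.001 within 10,000 kb | near-independence of instruments; window gates the LD test |
| weak-instrument filter | drop F < 10 (strict <) | conventional weak-instrument bound |
| minimum instruments | 2 | a single Wald ratio admits no heterogeneity diagnostics |
| F-statistic mode | `z_based` (r² = z²/(z²+n)) | robust when EAF is missing; `eaf_based` (2·eaf·(1−eaf)·β²) available and recorded in the run manifest |

Clumping visits variants by ascending p-value with ties broken by
(chromosome, position, variant id), so the kept set is independent of input
row order. Variants absent from the LD matrix are treated as unlinked and
counted in the log.

## Harmonization

Outcome records are aligned to the exposure's allele coding; swapped coding
flips the outcome beta and EAF; strand complements (A↔T, C↔G) are tried
before declaring a mismatch. Palindromic (A/T, C/G) variants are dropped by
default (`drop_all`), since their strand is unresolvable from alleles alone;
the `eaf_infer` policy instead keeps pairs whose EAFs both fall outside
(0.42, 0.58) and orients them by minor-allele agreement. The policy in force
is recorded with the output. Outcome-side significance filtering (removing
variants genome-wide significant for the outcome) is deliberately not
applied.

## Estimator numerics

* IVW defaults to multiplicative random effects: SE scaled by
  max(1, √(Q/(k−1))), so it never undercuts the fixed-effect SE. p-values
  are two-sided normal.
* Egger orients pairs to β̂X ≥ 0 before fitting, uses weights 1/σ²Y, bounds
  the residual scale below at 1, and uses t-distribution p-values on k−2 df.
  With very weak instruments (|z| ≲ 2) the orientation step can flip pairs
  by noise; the selection cascade's F ≥ 10 screen is assumed to have run
  first.
* The weighted median interpolates the ratio at cumulative mid-point weight
  1/2; its SE is a parametric bootstrap (default 1000 draws, explicit seed;
  `n_boot=0` skips the SE inside large simulations).
* Mode estimators use a normal kernel with bandwidth = factor × 1.4826·MAD
  of the ratios (factor 1 by default), a 2048-point grid spanning the ratios
  ± 3 bandwidths, and break argmax ties toward the median ratio. Bandwidth
  and bootstrap settings are package choices, documented here, not inherited
  from any particular prior analysis.
* MVMR is weighted multivariable regression through the origin; a
  rank-deficient design raises a collinearity error rather than returning
  arbitrary coefficients.
* BH-FDR is the literal step-up definition, applied within each exposure
  family (taxa, bacterial pathways, metabolites) as configured by the
  caller; family sizes are never inferred.
* CIs are exp(β ± 1.96·SE) throughout.

## Sensitivity battery

* Cochran's Q uses the fixed-effects IVW center; radial MR's per-variant Qj
  (first-order weights) sums exactly to Q, and flags variants at the
  upper-α χ²(1) point (α = 0.05 default). Modified second-order weights are
  out of scope.
* MR-PRESSO: observed statistic is the weighted RSS of outcome effects about
  leave-one-out IVW fits; the null is simulated by redrawing outcome effects
  about those fits (global p uses the (1+#)/(n_sim+1) correction). Per-SNP
  outlier p-values are raw empirical proportions — they can reach zero,
  which keeps Bonferroni-corrected detection workable at n_sim = 500–1000 —
  so occasional lone false flags are expected under the null at modest
  n_sim. The distortion test compares the outlier-removal shift against
  random same-size removals. Defaults: n_sim = 1000, outlier α = 0.05.
* Steiger uses the z²/(z²+n) pseudo-R² on both sides (an approximation on
  the log-odds scale for binary outcomes) and a two-sample z-test on the
  difference of Fisher-transformed √R².
* Power for binary outcomes is the normal-approximation closed form
  Φ(z*−z₁₋α/₂) + Φ(−z*−z₁₋α/₂) with z* = |ln OR|·√(n·r²·cf·(1−cf)); it is
  an approximation to more elaborate published calculators.

## Mediation

The two-step decomposition takes β3 (total) from exposure→outcome IVW on the
exposure's instruments, β1 from exposure→mediator IVW on the same
instruments, and β2 from mediator→outcome IVW on the mediator's own
instruments — univariable throughout, which is what makes the product
arithmetic exact; an MVMR-based β2 is available for sensitivity. The
indirect effect's p-value attaches to the indirect effect itself (the
Delta-method z-test); the mediated proportion is computed on the log-odds
scale, converting odds ratios before division. When indirect and total
effects disagree in sign the proportion is withheld and the result is
flagged as inconsistent mediation, since a negative "share" has no
interpretation.

## LD-score regression

Univariate: weighted regression of χ² on ℓ with a free intercept; weights
1/(2·(1+n·ĥ²·ℓ/M)²), initialized unweighted and iterated twice. Cross-trait:
z-score products regressed on ℓ with a free intercept (absorbing sample
overlap); rg = ρ̂g/√(ĥ²₁·ĥ²₂). SEs and the rg p-value come from a
delete-one-block jackknife over 50 contiguous blocks (configurable). At
least 200 variants are required. Non-positive heritability leaves rg flagged
"not evaluable" instead of crashing. The reference LD scores are taken as
exact inputs; no HapMap-style variant filtering is applied.

## Enrichment

P(X ≥ h) with the hypergeometric upper tail (not > h). The background size N
is explicit per-library configuration; `infer_background` inverts the
expected-hit relation N = K·n/expected for libraries that publish expected
counts but not N. The significance mark defaults to 0.10, the customary
threshold for pathway-level screens. Known limitation: multi-hit rows from
some published tools do not match this exact tail (they appear to use a
different approximation), so cross-checks against printed tables should use
single-hit rows.

## Synthetic GWAS generator

The generator emulates three non-overlapping summary-statistic studies with
defaults matching the study designs it stands in for: exposure n = 7,738
(gut-microbiome GWAS scale), mediator n = 8,299 (blood metabolites), binary
outcome with 29,266 cases / 56,450 controls (lung cancer), simulated
directly on the log-odds scale with effective size 4/(1/n_case+1/n_control)
— no individual-level liability simulation. Per variant, MAF ~
Uniform(0.05, 0.5), true exposure effects are half-normal and rescaled so
the realized heritability is exact (h² = 0.2 over 50 instruments by
default, giving mean instrument F ≈ 30, i.e. the strength instruments have
after locus-wide-significance and F ≥ 10 screening). Drawing effects
positive encodes the convention that effect alleles are oriented to the
exposure-increasing allele; this is what makes "directional" pleiotropy
directional after Egger's orientation step. The mediator carries its own
instruments (needed for the mediator→outcome leg to be identified) plus the
inherited β1·b effects; outcome effects are θ·b + β2·c + α with
θ = δ + β1·β2 enforced. Pleiotropy is InSIDE-satisfying by default
(αj ~ N(μα, σα²) on a random invalid subset, independent of b; σα = 0.02
when μα = 0.05 in the stress tests); a correlated-pleiotropy switch exists
for stress testing only. LD blocks share noise correlation √r² so
within-block z-score r² equals the configured value, and LD scores are the
analytic 1 + (block−1)·r². A fifth of variants are palindromic with EAF in
(0.4, 0.6) so the strand ambiguity is real. One master seed spawns
deterministic per-study substreams, so the three studies never share noise
(no sample overlap).

What the generator does not emulate: realistic microbiome taxon abundance
distributions, genotype-level LD, allele-frequency mismatch between
studies, population stratification, or sample overlap (beyond what the LDSC
intercept would absorb). Passing tests therefore demonstrate correctness of
the estimators under their own assumptions, not robustness to every failure
mode of real cohort data.

## Verification problem sizes

The statistical acceptance tests run at sizes chosen to keep the whole suite
desk-scale while leaving Monte-Carlo error well inside the asserted
tolerances: 500 replicates × 50 instruments for estimator recovery and CI
coverage, 1000 for type-I error, 20 batches × 10 replicates for the
pleiotropy comparisons, 100 + 200 replicates (n_sim = 500) for MR-PRESSO,
200 + 200 for Steiger, 100 replicates at M = 2000 variants and n = 20,000
for LDSC, and 200 replicates of 30 + 30 instruments for mediation recovery.
LDSC verification uses block sizes cycling 1..10 (r² = 0.8) because spread
in ℓ is what identifies the slope; uniform blocks would be nearly collinear
with the intercept.

## Known limitations

* First-order Wald SEs ignore exposure-side noise, so IVW coverage sits
  slightly below nominal (≈0.94) when mean instrument F ≈ 30; this is the
  standard behavior of the estimator, not corrected for.
* The Egger intercept's meaning degrades if instruments with F < 10 are fed
  in despite the selection cascade.
* MR-PRESSO's empirical outlier p-values are granular at small n_sim.
* LDSC here is the plain (unpartitioned) model with exact synthetic LD
  scores; it is not a replacement for reference-panel LDSC on real data.
* The proportion-mediated SE is Delta-method-optional output; inference on
  ratios of estimates near zero total effect is unstable by nature.
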