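# mrpipe

A tested, reusable Python implementation of the full causal-inference
workflow used in two-sample Mendelian randomization (MR) studies of the gut
microbiome, blood metabolites and disease risk — instrument selection,
harmonization, a five-estimator MR battery with sensitivity diagnostics,
two-step mediation with Delta-method inference, LD-score regression, and
metabolite pathway over-representation — together with a synthetic GWAS
generator so every stage can be exercised end-to-end against known ground
truth, without downloading any real summary statistics.

It is written for epidemiologists and statistical geneticists who work with
GWAS summary statistics (per-variant β, SE, p, EAF, N) and want a scriptable,
deterministic pipeline rather than a collection of one-off R sessions.

## The statistics at the core

Given instruments j = 1..k harmonized to a shared effect allele, with
exposure effects β̂X,j (SE σX,j) and outcome effects β̂Y,j (SE σY,j):

* **Wald ratio** β̂j = β̂Y,j/β̂X,j with first-order SE σY,j/|β̂X,j|.
* **IVW** (primary): β̂IVW = Σ wj β̂j / Σ wj with wj = 1/SE(β̂j)²;
  multiplicative random effects scale the SE by max(1, √(Q/(k−1))) where
  Q = Σ wj (β̂j − β̂IVW)² is Cochran's Q.
* **MR-Egger**: weighted regression β̂Y,j = α + β·β̂X,j; the slope is robust
  to directional pleiotropy under InSIDE, the intercept α tests it.
* **Weighted median**: interpolated 50th percentile of the ratio
  distribution under IVW weights; consistent when valid instruments carry
  more than half the weight. **Simple/weighted mode**: argmax of a normal-
  kernel density over the ratios.
* **Sensitivity**: MR-PRESSO (simulation-based global/outlier/distortion
  tests), radial MR (per-variant Q decomposition), leave-one-out, the
  Steiger directionality test, and a closed-form power approximation for
  binary outcomes.
* **Two-step mediation**: indirect effect β1·β2 (exposure→mediator times
  mediator→outcome), Delta-method SE √(β1²se2² + β2²se1²), mediated
  proportion β1·β2/β3 on the log-odds scale.
* **LD-score regression**: E[χ²j] = 1 + N·h²·ℓj/M for SNP-heritability;
  E[z1j z2j] = √(N1N2)·ρg·ℓj/M for genetic correlation, with
  delete-one-block jackknife standard errors.
* **Enrichment**: hypergeometric upper tail P(X ≥ h) for h query hits in a
  pathway of K members against a background universe of N compounds.

Instrument selection follows the conventional five-step cascade: p < 1×10⁻⁵
(locus-wide significance), greedy LD clumping at r² < 0.001 within a
10,000 kb window, palindrome/mismatch exclusion at harmonization, removal of
instruments with F < 10, and removal of variants on a local confounder
blocklist (e.g. smoking, alcohol, air pollution), requiring at least two
surviving instruments per exposure.

## Worked example

```python
from mrpipe import SimulationConfig, simulate_study_set, harmonize, run_all_methods
from mrpipe.mediation import two_step_pipeline

cfg = SimulationConfig(m_variants=30, m_mediator=30, theta=0.2,
                       beta1=0.3, beta2=0.4, seed=3)
study = simulate_study_set(cfg)

hs = harmonize(study.exposure, study.outcome)
for r in run_all_methods(hs, n_boot=200):
    print(f"{r.method:16s} OR={r.or_:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}) p={r.pval:.2e}")

med = two_step_pipeline(study.exposure, study.mediator, study.outcome, ld=study.ld)
print(f"indirect={med.indirect:.4f}  proportion mediated={med.proportion:.3f}")
```

prints (exact values depend on the seed):

```
ivw              OR=1.197 (1.072-1.335) p=1.33e-03
egger            OR=1.249 (1.074-1.454) p=6.05e-03
weighted_median  OR=1.220 (1.186-1.254) p=3.25e-43
simple_mode      OR=1.202 (0.839-1.723) p=3.16e-01
weighted_mode    OR=1.228 (0.210-7.183) p=8.20e-01
indirect=0.1129  proportion mediated=0.564
```

Here the generating total effect is θ = 0.2 log-odds per SD (OR ≈ 1.22), so
the five estimators agree with each other and with the truth, and the
recovered mediated proportion is close to the generating
β1·β2/θ = 0.3·0.4/0.2 = 0.6.

The same stages are available from the shell:

```bash
mrpipe simulate --seed 11 --out sim/
mrpipe mr sim/exposure.tsv sim/outcome.tsv --ld sim/ld_matrix.tsv --out mr.tsv
mrpipe run-all --seed 2 --out fullrun/    # forward+reverse MR, MVMR, mediation, LDSC
```

## Layout

| module | contents |
|---|---|
| `mrpipe.sumstats_io` | TSV readers/writers, validation, LD matrix/scores, gene-map annotation |
| `mrpipe.synthetic_gwas` | synthetic exposure/mediator/outcome triplets with known truth |
| `mrpipe.iv_selection` | p-value filter, greedy clumping, R²/F statistics, confounder removal |
| `mrpipe.harmonization` | allele alignment, palindrome policies, Wald ratios, multi-exposure sets |
| `mrpipe.mr_estimators` | IVW, Egger, weighted median, modes, MVMR, BH-FDR |
| `mrpipe.sensitivity` | Cochran Q, MR-PRESSO, radial MR, leave-one-out, Steiger, power |
| `mrpipe.mediation` | Delta-method indirect effects, mediated proportion, screens, verdicts |
| `mrpipe.ldsc` | SNP-heritability and genetic correlation with block jackknife |
| `mrpipe.enrichment` | hypergeometric over-representation, background inference |
| `mrpipe.pipeline` / `mrpipe.cli` | orchestration, manifests, `mrpipe` subcommands |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
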