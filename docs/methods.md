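# Methods

## Problem setting

Small clinical cohorts (order 10²–10³ samples) genotyped genome-wide are
underpowered for variant-by-variant association at genome-wide
significance. The pipeline implemented here trades the genome-wide search
for a two-step design: first retain only variants showing clinical
association at a permissive threshold, then test genes (sets of retained
variants) with a variance-component kernel test whose per-variant weights
come from an external reference population. The stages are independent
library calls; the pipeline driver only sequences them.

## Stage 1 — per-variant tests

All tests are complete-case per variant: samples with a missing genotype
at that variant are dropped, and `NMISS` reports the non-missing count
actually used (PLINK's convention for that column).

- **Genetic models.** Dosage of the counted allele A1 (always the
  in-sample minor allele, re-oriented after load; ties at 0.5 keep the
  file's orientation) is coded additively (0/1/2), dominantly (0/1/1) or
  recessively (0/0/1). Missing entries pass through.
- **Allelic tests.** Fisher exact and Pearson chi-square act on the 2×2
  allele-count table built by counting each non-missing genotype as two
  independent alleles (a Hardy–Weinberg assumption). Two-sidedness of the
  exact test follows the point-probability rule (sum over tables with
  fixed margins whose probability does not exceed the observed table's),
  the convention of mainstream statistical software. The chi-square test
  applies no continuity correction by default. Odds ratios for tables
  with a zero cell are reported with the Haldane–Anscombe +0.5
  correction; p-values are untouched by it.
- **Trend test.** Cochran–Armitage with scores (0, 1, 2) in score-test
  form: `T = Σ sᵢ(rᵢ − nᵢR/N)`, `Var T = (R/N)(1 − R/N)[Σ nᵢsᵢ² −
  (Σ nᵢsᵢ)²/N]`, `T²/Var T ~ χ²₁`, conditioning on the genotype column
  totals. This equals the textbook ratio form algebraically (verified in
  tests against an independently coded version).
- **Regressions.** Logistic (Wald z, OR = exp β), linear (t), Cox PH
  (Breslow ties, Wald z, HR = exp β) and the log-rank test across
  genotype groups. Fits are delegated to statsmodels/lifelines;
  hand-rolled IRLS and normal-equation oracles in the test suite verify
  them on small fixtures. Separation and non-convergence yield flagged
  records with the reason, never a fabricated p.
- **Genomic inflation.** λ = median(χ²-transform of p)/0.4549364, the
  1-df chi-square null median. λ ≈ 1 on null data supports the chosen
  pre-filter threshold.

The pre-filter threshold defaults to p < 0.05 and is exposed everywhere;
a permissive threshold is deliberate, since stage 4 provides the
inference and a tight filter risks false negatives.

## Stage 2 — annotation and over-representation

Variants map to every gene whose interval (optionally flanked by
`flank_bp`, default 0 — strict gene-body overlap) contains their
position; overlapping genes all receive the variant (no nearest-gene
tie-break). Coordinates are 1-based inclusive internally; BED input is
converted from 0-based half-open at read time; chromosome labels are
normalized ("chr1" ≡ "1").

Over-representation uses the upper-tail hypergeometric probability of
drawing ≥ k set members among the n query genes from a universe of N
containing M; the universe defaults to all genes appearing in the GMT
collection and can be supplied explicitly. p-values are BH-adjusted
across the sets reported. The q-value column uses Storey's estimator
with a λ grid 0.05–0.95 and a cubic-spline smooth of π₀(λ); with few
tests π₀ falls back to min(1, 2·mean p). Exact agreement with any other
q-value implementation is not a goal; the estimator is documented here
instead.

## Stage 3 — collapsing weights

The logistic weight `w = exp(−x₁)/(1 + exp(−x₁))`, `x₁ = (MAF − W1)·W2`,
is evaluated through a numerically stable sigmoid (no overflow for |x₁|
up to 10⁴ and beyond). Defaults W1 = 0.07 (the half-weight MAF) and
W2 = 150 (slope): weight > 0.99 below MAF ≈ 0.037 and < 0.01 above
MAF ≈ 0.103, a smooth rare-up/common-down transition rather than a hard
cutoff. A reference MAF of 0 (site known, variant absent) is valid and
yields the maximal weight — the rarest variants matter most. MAF-side
conventions: frequencies above 0.5 in a reference table are folded with
a warning; lookups match (chrom, pos, ref, alt) and retry with ref/alt
swapped, since allele orientation differs across population resources.
Unmatched variants follow a policy — in-sample MAF (default, logged),
exclusion, or unit weight — because silently dropping variants would
change the gene-level marker counts.

## Stage 4 — kernel association test

Null model: logistic (dichotomous) or least-squares (continuous)
regression of the outcome on covariates only, intercept always included.
With residuals r, the statistic is `Q = rᵀGW²GᵀR` computed in the
m-vector form `‖(GW)ᵀr‖²` (the n×n kernel form is algebraically
identical and checked in tests); continuous-outcome Q is divided by
σ̂² = RSS/(n−p) so one reference distribution serves both families.

Under H₀, Q ~ Σλⱼχ²₁ with λⱼ the eigenvalues of `W Gᵀ P₀ G W`:
`P₀ = V − VX(XᵀVX)⁻¹XᵀV` (V = diag(μ̂(1−μ̂))) for dichotomous outcomes,
the hat-matrix complement for continuous ones. Numerically negative
eigenvalues below 1e-10 of the largest are clipped to zero.

**Tail evaluation.** The default engine numerically inverts the
mixture's characteristic function: p = 1/2 + (1/π)∫₀^∞ sin θ(u)/(u ρ(u)) du
with θ = (Σ atan λⱼu − qu)/2 and ρ = Π(1 + λⱼ²u²)^¼. One eigenvalue
reduces exactly to a scaled χ²₁. For m ≥ 2 the integral is split at a
point past the arctan transition: adaptive quadrature below, and above
it sin θ is expanded against the slowly varying phase so QUADPACK's
oscillatory Fourier integrator handles the tail. If the inversion fails
its error bound or leaves (0, 1], the Liu four-moment (non-central
chi-square matching) approximation is used instead and the fallback is
recorded in the output row — in the deep tail (p ≲ 1e-12) this is the
normal path. Monte-Carlo sampling of the quadratic form and outcome
permutation (valid only for intercept-only nulls, and refused otherwise)
serve as independent oracles in tests, never as the default engine.

**QC inside the test.** Missing dosages are mean-imputed (2×in-sample
MAF); variants monomorphic after imputation are dropped.
`N.Marker.All` counts set members present in the genotype file before
QC, `N.Marker.Test` the post-QC count. Set members absent from the
genotype data are logged and excluded from both. When no weight table is
supplied, weights default to the Beta(1, 25) density of the in-sample
MAF. Raw p-values are reported; an optional BH column is available but
no correction is applied by default.

## Synthetic data

The generator emulates the target study type: n = 500 samples,
m = 1000 variants in 100 genes by default, MAF uniform on [0.005, 0.3]
(rare through common), genotypes binomial under Hardy–Weinberg, 1%
missingness, sex/age covariates, and null/logistic/linear/exponential-
survival outcome models. Defaults were fixed once to represent a
realistic small clinical cohort. Reference MAF tables add binomial
resampling noise at a configurable panel size (default 10⁴ diploids),
emulating imperfect external frequencies. Variants are independent
across sites by default; an optional Markov allele-copying block mode
provides LD structure for the LD heatmap. What this does **not**
emulate: coalescent-realistic haplotypes, population stratification,
genotyping batch effects, or imputation uncertainty — so passing
calibration here shows the statistics are correct under their stated
assumptions, not that real-data confounding is handled.

## Numerical and design choices

- Missing genotypes carry a dedicated sentinel (−1 in the int8 matrix),
  never −9 or a zero stand-in; every downstream test sees explicit
  missingness.
- Sample-major PLINK .bed files are rejected, not transposed; truncated
  payloads and bad magic bytes are format errors.
- Multi-allelic VCF records are rejected by default.
- The Cochran–Armitage test is exposed as method `trend` alongside the
  regression menu.
- The gene-level outcome flag follows the standard convention
  D = dichotomous (logistic null), C = continuous (linear null).
- Every stochastic routine takes an explicit seed; the pipeline seed is
  recorded in the manifest, and reruns with the same config produce
  byte-identical CSVs.
- Problem sizes in the validation suite — 1000-variant scans, 2000 null
  genes at n = 500, B = 1999 permutations, 10⁶-draw Monte-Carlo oracles,
  100–120 power replicates — were chosen as the smallest sizes at which
  binomial/KS checks are informative at their stated confidence levels.

## Known limitations

No SKAT-O rho-grid combination, burden-only tests, small-sample moment
adjustments, or related-sample models. No BGEN/PGEN, phased, or dosage
(non-integer) genotypes. Allelic tests assume HWE within groups; the
genotypic 2×3 test is not provided. The permutation oracle requires
exchangeability (no covariates). Pre-filtering and final testing on the
same data inflate gene-level type-I error relative to split-sample use;
the pipeline mirrors that design intentionally, and the calibration
results apply to the unfiltered test.
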