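# Methods

## Scope and model overview

`feednet` analyses feed efficiency in growing beef cattle through
three criteria — residual feed intake (RFI), residual gain (RG) and
the feed efficiency ratio (FE = ADG/FI) — and asks which genes their
genetic determinisms share. The chain is: residual-trait construction,
fixed-effect precorrection, mixed-linear-model association per variant,
association-weight-matrix (AWM) gene selection keyed on each
criterion, and quantification of the selected SNP panels by z-score
genomic correlations and GREML SNP heritability against random panels.

## Trait construction

ADG is the slope of the endpoint weights over the test period,
`(final − initial)/days`. The mid-test weight is the arithmetic mean of
the endpoint weights (the standard convention when only endpoint
weights enter the model); MMW = mid-test weight^0.75 proxies
maintenance requirements. RFI and RG are OLS residuals of

    FI  = year + β1·MMW + β2·ADG + β3·final_age + RFI
    ADG = year + β1·MMW + β2·FI  + β3·final_age + RG

with year (contemporary group) as a categorical fixed effect. OLS
orthogonality makes RFI uncorrelated with MMW and ADG, and RG with MMW
and FI, within the fitted sample — the defining property of residual
criteria, asserted by the test suite to 1e-8. Residual-trait fits
require a full-rank design and report the collinear terms otherwise.

Before association, all six traits (RFI, RG, FE, FI, FW, ADG) are
precorrected by OLS on year + dam-age class + twinning + final-age
covariate. RFI/RG are computed on raw traits first and then
precorrected with the rest: the residual-trait models and the GWAS
covariate set are two distinct model statements, and conflating them
would silently change the year-adjustment of RFI. In the precorrection
step rank deficiency is benign (projection residuals are unique), so a
redundant dummy coding — e.g. a single-year data set with a constant
age — degrades gracefully to mean-centering instead of erroring.

## Variant QC

Per-variant call rate, MAF and an exact Hardy–Weinberg test
(enumeration of heterozygote counts conditional on allele counts) are
computed from hard genotypes. Retention rules: call rate ≥ 0.90, MAF
strictly > 0.01, HWE exact P ≥ 1e-4 (strong deviations removed), and
imputation R² strictly > 0.30 when a quality column is supplied.
Strict inequalities for MAF and R² follow the "higher than" reading;
boundary behaviour is pinned by tests.

## Genomic relationships and REML

The GRM is VanRaden method 1: `G = ZZ′ / (2Σp(1−p))` with
frequency-centred dosages, monomorphic variants excluded and missing
genotypes mean-imputed (logged). Under random mating the mean diagonal
is ≈ 1, asserted within ±0.05 at n=1000/m=2000.

Null-model variance components for `y = 1μ + u + e`,
`u ~ N(0, G σu²)`, are REML estimates obtained by eigendecomposing G
once and profiling the restricted likelihood down to
h² = σu²/(σu²+σe²):

    -2 lR(h²) ∝ (n−1)·log σ̂p² + Σ log v_i + log Σ x̃0i²/v_i,
    v_i = h²·d_i + (1−h²)

with d the GRM eigenvalues and x̃0 the rotated intercept. A bounded
Brent search over h² ∈ [0, 1] maximizes this exactly (one random
effect ⇒ the profile is one-dimensional), with an explicit boundary
check at h² = 0; total variance is profiled analytically. This
formulation cannot diverge, unlike quasi-Newton variance updates, and
matches a dense-matrix grid-search oracle to < 1e-4 in log-likelihood
on n = 50 fixtures. The SE of h² is a delta-method transform of the
inverse Fisher (average-information) matrix of (σu², σe²) computed in
the rotated basis. Variances are floored at 1e-8.

## Mixed-linear-model association

Per variant, generalized least squares of y on [1, x] with
`V = G σu² + I σe²` held fixed at the null-model estimates (the
standard MLMA scheme: variance estimated once per trait, then fixed).
The GRM rotation diagonalizes V, so each variant costs O(n); the
per-variant normal equations are batched as matrix products.
z = b/se, with two-sided normal P-values. When σu² = 0 the test
reduces exactly to OLS (oracle-checked to 1e-8). Monomorphic variants
are flagged and emitted with z = 0, p = 1 rather than dropped, keeping
the variant universe stable across traits — the AWM step requires it.
Type-I error under a global null is calibrated (P < 0.05 fraction
within 0.05 ± 0.02 at 2000 variants, n = 500).

The Bonferroni helper returns −log10(α/m); at sequence scale
(m = 8,602,123, α = 0.05) it prints 8.24.

## AWM construction and gene selection

Stages, keyed on one criterion at a time:

1. rows = variants with key-trait P ≤ 0.001 (inclusive boundary);
2. retained traits = those whose z-scores over the stage-1 rows have
   |Pearson r| ≥ 0.25 with the key trait's (computed over stage-1 rows
   only; Pearson chosen as the default correlation of standardized
   effects); the key trait is always retained;
3. secondary rows = remaining variants with P ≤ 0.001 for at least two
   retained non-key traits (the key does not count);
4. SNPs are assigned to genes strictly within gene bodies (1-based
   closed coordinates after normalizing BED input; overlapping genes
   resolved by nearest gene midpoint, ties by smaller start);
   intergenic SNPs stay unassigned and are reported separately;
5. per gene, the SNP associated with the most traits wins; ties break
   by the lowest cumulated P-value over the SNP's associated traits
   (arithmetic sum of raw P by default, a −log10 variant behind
   `cum_p_mode`), then by genomic position.

An empty key-SNP set yields an empty matrix with a warning, not an
exception: a scan with no sub-threshold variants is a legitimate
outcome at small n. The whole procedure is verified against an
exhaustive plain-python restatement of the rules on ≤ 20-variant
instances, and the three-way gene-count partition
(key-only + key-and-other + other = total) is asserted on every run.

## Panel quantification

Genomic correlations are Pearson correlations of the AWM z-score
columns over all matrix rows (≥ 3 rows required), one matrix per AWM
run. GREML SNP heritability of a panel builds a GRM from the subset
only and re-runs the REML above. The contrast draws an equal-size
random control panel without replacement from the non-selected
variants — uniformly by default; optionally MAF-matched by greedy
nearest-MAF assignment without replacement, which keeps the control
panel's MAF profile close even for skewed panels.

## Synthetic populations

The generator emulates the study design the pipeline targets: a
genotyped fattening population of Charolais young bulls.

* **Genotypes**: biallelic dosages from latent-uniform haplotype
  copying — within an LD block each haplotype copies its latent draw
  from the previous variant with probability `ld_strength` (default
  0.8) or redraws; marginal allele frequencies are exact
  (MAF ~ U(0.05, 0.5) by default) and adjacent variants are positively
  correlated. Blocks (default 10 variants) never span chromosome
  boundaries (29 autosomes by default). An optional sire-family mode
  transmits intact paternal haplotypes from a configurable number of
  sires; no default family count is claimed since the emulated
  population's structure is not parametrically described.
* **Traits**: base traits FI, ADG, FW with means/SDs 10.63 ± 1.23
  kg DM/d, 1.44 ± 0.19 kg/d, 695 ± 87 kg; heritabilities 0.35 each;
  genetic correlations r_g(FI,ADG) = 0.44, r_g(FI,FW) = 0.76,
  r_g(ADG,FW) = 0.80. Causal effects (default 300 of 20,000 variants)
  are multivariate normal across traits with that correlation —
  complete pleiotropy, so cross-trait z-score correlations exist for
  the AWM step to find; `private_causal_fraction` creates
  trait-specific causal variants instead. Genetic values are rescaled
  to exactly h²·σ_P² of realized variance (residuals are drawn, not
  rescaled), which makes parameter-recovery tests well-posed;
  residuals are uncorrelated across traits, so phenotypic correlations
  equal h·r_g·h and are weaker than typically observed in real
  fattening data — a deliberate simplification. RFI/RG/FE are *not* simulated: they emerge from the
  trait-derivation code, so their heritabilities and mutual
  correlations are outcomes, not inputs.
* **Fixed effects**: 22 year classes and 4 dam-age classes with
  effects ~ N(0, (0.5 σ_P)²) per class (large enough to matter,
  small enough not to dominate), twinning ~ Bernoulli(0.04) with a
  −0.3 σ_P offset (twins grow slower), final age ~ N(455, 10) days
  with a 0.25 σ_P-per-age-SD slope; test duration 180 days (test
  start ≈ 275 d, tested to ≈ 15 months). Initial weight is backed out
  as FW − ADG·days so the derivation chain is exactly consistent.
* **Annotation**: non-overlapping gene intervals placed one per
  equal-width window per chromosome, sized to cover a target fraction
  of variants (default 0.35, consistent with roughly a third of
  selected SNPs falling inside gene bodies in cattle WGS analyses).

What the generator does **not** emulate: linkage maps and recombination
(LD is block-local and distance-free), pedigree depth beyond optional
sire families, selection or assortative mating, imputation error
beyond an optional uniform R² column, residual correlations between
traits, and dominance/epistasis. Passing tests therefore demonstrate
the correctness and calibration of the estimators and selection rules
under a clean additive architecture — not robustness to confounding,
stratification or imputation artefacts in real cattle data.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced scale chosen to keep
the full suite in the tens of seconds while leaving the estimators
well-conditioned: REML oracle checks at n = 50, heritability recovery
at n = 1000 × 1000 SNPs over 10 seeds, type-I calibration at
n = 500 × 2000 SNPs, panel contrasts at n = 1000 × 2000 SNPs with 50
causal variants, and the end-to-end pipeline at n = 600 × 4000 SNPs.
The library defaults remain at the emulated-population scale
(789 × 20,000).

Ties in variant rankings break by (chromosome, position) for
determinism. GRM eigenvalues are clipped at zero (they are ≥ −1e-6 by
construction); REML convergence tolerance is 1e-10 on h², maximum 100
evaluations; P-values are clipped away from 0 to stay in (0, 1].
Every stochastic component takes an explicit seed, and the pipeline
manifest records config hashes and output checksums so identical
configurations reproduce byte-identical outputs.

## Known limitations

* Genomic correlations from z-scores are a summary-statistic proxy;
  they are not bivariate-REML genetic correlations and can exceed them
  in magnitude over selected (winner's-curse-affected) variant sets.
* The MLMA uses a single whole-genome GRM (no leave-one-chromosome-out
  correction), so tests of variants inside strong GRM-tagged signals
  are slightly conservative (proximal contamination).
* The AWM assigns SNPs strictly within gene bodies; regulatory
  variants outside genes are never attributed to a gene.
* Single-trait precorrection then MLMA ignores uncertainty propagated
  from the residual-trait regressions.
* Downstream ontology/pathway enrichment of the selected genes is out
  of scope; the gene tables are the hand-off point.
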