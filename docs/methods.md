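# Methods

## Model and assumptions

The package implements two-sample Mendelian randomization with pQTL
instruments.  The exposure is a circulating protein concentration measured
in one cohort; the outcome is disease status from an independent
case-control GWAS.  Per-protein causal effects are estimated by the
fixed-effects IVW formula

beta = Σᵢ βᵢ,GX βᵢ,GY σᵢ,GY⁻² / Σᵢ βᵢ,GX² σᵢ,GY⁻²,  se = (Σᵢ βᵢ,GX² σᵢ,GY⁻²)^(−1/2),

equivalent to weighted least squares of βGY on βGX through the origin with
weights σGY⁻².  The estimand is a log-OR per SD of genetically predicted
protein.  Identification rests on the usual instrumental-variable
assumptions: instruments associate with the protein (enforced by the
catalog significance threshold), are independent of confounders, and affect
disease only through the protein.  The estimator is first-order ("no
measurement error"): exposure-side standard errors do not enter the weights
or the SE.  With strong instruments (the catalog threshold implies
F-statistics in the hundreds) the resulting CI undercoverage is small; the
calibration study below quantifies it (~93–95% empirical coverage of the
nominal 95% interval).  A single-SNP instrument reduces exactly to the Wald
ratio βGY/βGX with se σGY/|βGX|.

Inference is normal-theory throughout: two-sided p-values from the standard
normal, CI multiplier fixed at 1.96.  This matches the fixed-effects
framework of the analyses the pipeline reproduces, and makes a printed
OR/CI pair invertible to its p-value (`p_from_or_ci`), which the
consistency-report stage uses to audit result tables.

## Pipeline stages and key parameters

| parameter | default | meaning |
|---|---|---|
| `pqtl_p_threshold` | 1.5e-11 | catalog significance required of an instrument (the source catalog's genome-wide pQTL threshold) |
| `r2_threshold` | 0.1 | maximum pairwise LD among instruments of one protein |
| `palindrome_eaf_window` | 0.08 | A/T and C/G SNPs are dropped when min(EAF, 1−EAF) is within this window of 0.5 in either source |
| `fdr_alpha` | 0.05 | BH significance level across the protein panel |
| `collinearity_r2` | 0.9 | conditional analysis refuses targets this correlated with the conditioning set |
| `freq_diff_threshold` | 0.2 | max allele-frequency discrepancy between panel and summary statistics |

**Harmonization.** Records are matched on snp_id and allele set.  Identical
(effect, other) pairs pass through; swapped pairs flip the outcome beta's
sign and complement its EAF; palindromic SNPs with MAF near 0.5 are dropped
as strand-ambiguous; no strand inference from frequency or flanking
sequence is ever attempted.  Harmonization precedes pruning, so LD pruning
ranks only SNPs that can actually contribute.

**Pruning.** Greedy p-value-ranked clumping (ties broken lexicographically
by snp_id): keep the best remaining SNP, discard everything at r² ≥
threshold against it, repeat.  The retained set is pairwise r² < threshold
by construction and invariant to input order.  Pairs on different
chromosomes are defined independent without computation.  r² is the squared
Pearson correlation of reference-panel dosages (missing dosages mean-imputed
per column).  A SNP absent from the panel is retained only when it is the
sole candidate on its chromosome; otherwise it is excluded with a
diagnostic — failing closed avoids accidentally correlated instruments.

**Multiple testing.** BH step-up adjustment across the full protein panel
(m_total = number of proteins tested), not per stratum; subtype analyses
report raw p-values only.  When only the top of the p-value distribution is
supplied (a published top-hits table), unobserved tests are padded at 0.5;
any pad at least as large as the largest observed adjusted value leaves the
observed adjustments unchanged, so the pad is inert for such tables.

**Conditional analysis.** Given marginal estimates, a conditioning SNP set,
reference LD r, allele frequencies p and per-SNP effective sample sizes
n (4/(1/cases + 1/controls) for case-control; log-ORs treated as
linear-scale effects), genotype cross-products are reconstructed as
r·√(DⱼDₖ) with D = 2p(1−p)n.  Joint coefficients of {target + conditioning
set} solve the reconstructed normal equations; the residual variance uses a
median-based estimate of the phenotype sum of squares across the involved
SNPs, and the conditional SE comes from the corresponding diagonal.  An
empty conditioning set is an exact identity.  Targets too collinear with
the conditioning set, or with discordant allele frequencies, are flagged
and not estimated; a singular conditioning LD block raises an error naming
the block rather than being ridge-regularized.  Only conditional
*estimation* given an explicit SNP list is implemented — stepwise model
selection is out of scope.  An instrument that is itself a conditioning
variant makes the protein's conditional result NA.

## Synthetic data

The generator emulates the study design end to end.  Genotypes: latent
Gaussian haplotypes with AR(1) correlation inside blocks (each block its own
chromosome), thresholded at Φ⁻¹(MAF) and summed in pairs, giving
Hardy–Weinberg dosages with tunable LD.  Thresholding attenuates dosage LD
relative to the latent correlation, increasingly so at low MAF.  The
protein is a sparse genetic score plus Gaussian noise with variance
1 − var(score) (floored at 0.05), so stated pQTL effects are per protein SD
up to O(n^−1/2); the realised protein is standardized before per-SNP OLS.
Disease follows a logistic model: logit(prevalence) + θ·(centered genetic
score) + optional per-SNP pleiotropic effects ~ N(0, pleiotropy_sd²) +
optional fixed risk-variant effects.  Cases and controls are sampled from a
population sized at 1.3× the implied requirement (or an explicit
`n_population`; an infeasible request errors).  Subtype labels partition
cases (default endometrioid share 0.75), with optionally distinct θ per
subtype via independent per-subtype liabilities.  Per-SNP summary
statistics come from closed-form OLS (exposure) and a vectorised
Newton–Raphson logistic fit (outcome), the latter validated against
statsmodels on reference datasets.  P-values are floored at 1e-300 to stay
in (0, 1].

The exposure cohort, outcome cohort, and LD reference panel are three
disjoint draws from one population model, so the two-sample assumption and
"external reference panel" structure hold by construction.  All randomness
flows through substreams of a single seed; regenerated bundles are
byte-identical.  Simulated allele pairs are non-palindromic by
construction so that ground-truth instruments survive harmonization (the
palindromic rule is exercised with explicit records in tests).

What the generator does *not* emulate: realistic MAF/LD spectra, imputation
noise, cryptic relatedness, population stratification, or winner's-curse
bias in catalog effect sizes.  Passing calibration here therefore shows the
estimator and plumbing are correct under the design assumptions, not that
real-data analyses are immune to those artifacts.

## Calibration study and problem sizes

The calibration scenario (`SimScenario.recovery_benchmark`) uses 30 SNPs in
6 AR(1) blocks (ρ = 0.6), one protein with three independent pQTLs (per-SD
effects 0.35/0.32/0.30, MAFs in 0.2–0.45 so every instrument clears the
catalog threshold at the exposure-cohort size), 3000 exposure individuals,
2000 cases/2000 controls at baseline prevalence 0.10, and θ = 0.2 (or 0 for
the null).  Across 200 replicates the mean IVW estimate sits within ±0.02
of θ, empirical 95% CI coverage lies in [0.92, 0.98] (slight undercoverage
is expected from the first-order estimator), and the null rejection rate at
α = 0.05 stays inside the exact binomial 99% interval.  The uniformity of
null per-SNP outcome p-values is checked by KS test on p-values pooled
across independent-SNP replicates.  The conditional-analysis oracle test
simulates individual-level data (n = 5000, 10 AR(1) SNPs) and requires
agreement with full multiple regression within 0.05 absolute.  The default
fixture scenario is desk-scale (3 proteins, 2000/2000);
`SimScenario.study_scale()` reproduces the published cohort sizes (3562
exposure; 12,906/108,979 outcome) for one-off large runs.

## Numerical and design choices

- Duplicate catalog rows for one (SNP, protein) pair keep the smaller-p row;
  the others are rejected with a line-numbered reason.  Readers never
  silently coerce: every row either parses or is rejected with its line.
- A p-value inconsistent with |beta/se| beyond 10% relative difference is a
  warning, not an error — published p-values are rounded.
- Positions are 1-based; chromosome labels are normalized by stripping a
  leading "chr"; files are tab-delimited UTF-8 with "NA" for missing, and a
  user-supplied column map keeps readers format-agnostic.
- Result tables print OR/CI at 2 decimals and p-values in scientific
  notation; record writers use shortest-round-trip float formatting so
  re-reading is lossless.
- Whether published analyses pruned before or after intersecting with
  outcome statistics is generally unstated; this package harmonizes first
  and prunes second (configurable order was considered and rejected to keep
  one deterministic, documented path).
- Conditional analysis is run for FDR-significant proteins by default (as
  published tables report), configurable to all proteins.

## Known limitations

- IVW only: no MR-Egger, weighted-median, or heterogeneity statistics, so
  directional pleiotropy is neither detected nor corrected.
- No proxy-SNP search: an instrument missing from a stratum's summary file
  is dropped, and a fully missing instrument yields an NA row, mirroring
  how such cells are reported in practice.
- No liftover, rsID resolution, or multi-allelic splitting; inputs are
  assumed on one genome build with consistent identifiers.
- Summary-statistic conditional estimates inherit reference-panel LD error;
  accuracy is asserted against an individual-level oracle, not against any
  particular external implementation.
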