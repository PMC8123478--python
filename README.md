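# pqtlmr

Proteome-wide two-sample Mendelian randomization (MR) from summary
statistics: build protein quantitative trait locus (pQTL) genetic
instruments, estimate per-protein causal effects on disease risk with the
fixed-effects inverse-variance-weighted (IVW) estimator, control the false
discovery rate across the protein panel, and re-estimate effects conditional
on known GWAS risk variants using approximate conditional analysis.

The package is aimed at genetic epidemiologists who have (a) a pQTL catalog
(one row per SNP-protein association, effects in protein SD per effect
allele), (b) case-control GWAS summary statistics for a disease (log-OR per
effect allele, optionally per histologic subtype), and (c) an LD reference
panel — and who want a deterministic, fully accounted-for pipeline from
those three inputs to a table of per-protein odds ratios.  A synthetic-data
module generates all three inputs with known ground truth, so every stage
can be validated end to end.

## The estimator

For protein *k* with harmonized instruments *i = 1..n*, where β<sub>i,GX</sub>
is the SNP effect on protein level (SD per allele), and β<sub>i,GY</sub>,
σ<sub>i,GY</sub> are the SNP effect on disease (log-OR per allele) and its
standard error, the causal log-OR per SD of genetically predicted protein is

```
beta = Σ_i β_i,GX β_i,GY σ_i,GY⁻²  /  Σ_i β_i,GX² σ_i,GY⁻²
se   = ( Σ_i β_i,GX² σ_i,GY⁻² )^(-1/2)
```

— weighted least squares of the outcome betas on the exposure betas through
the origin, reducing to the Wald ratio β<sub>GY</sub>/β<sub>GX</sub> for a
single SNP.  OR and 95% CI are `exp(beta)`, `exp(beta ± 1.96·se)`; two-sided
p-values come from the standard normal.  Exposure-side uncertainty is not
propagated (the first-order estimator); σ<sub>GX</sub> is kept for
diagnostics.

Around the estimator sit: allele harmonization (sign flips for swapped
codings, strand-ambiguous palindromic SNPs dropped near MAF 0.5), greedy
p-value-ranked LD pruning to pairwise r² < 0.1 within each chromosome,
Benjamini–Hochberg FDR across the protein panel, and summary-statistic
conditional analysis (LD-reconstructed normal equations, effective sample
size 4/(1/cases + 1/controls) for case-control traits).

## Worked example

`examples/` holds one narrative script per capability.  The two-SNP
estimate (`examples/01_ivw_basics.py`) prints:

```
rs1001: status=ok flip=False beta_gx=+0.420 beta_gy=+0.081
rs2002: status=ok flip=True beta_gx=+0.350 beta_gy=+0.064

IVW log-OR per SD: 0.1900 (SE 0.0363)
OR (95% CI): 1.21 (1.13-1.30)
p-value: 1.70e-07
p implied by OR/CI: 1.70e-07
```

rs2002's outcome record reported the opposite allele, so its log-OR sign
was flipped before pooling; each SD of genetically predicted protein then
multiplies disease odds by 1.21.  The full synthetic pipeline
(`examples/02_simulate_and_run_pipeline.py`) simulates a three-protein
study — a real effect (true log-OR 0.2/SD), a null protein whose only
instrument is itself a risk variant, and a protective effect — and prints:

```
overall analysis (5 instrument SNPs used, 0 dropped of 5 catalog pairs):
  PROT_A: OR 1.18 (0.99-1.41) p=5.77e-02 FDR=8.65e-02 cond_p=8.47e-02 [3 SNPs]
  PROT_B: OR 1.38 (1.06-1.81) p=1.79e-02 FDR=5.37e-02 cond_p=NA [1 SNPs]
  PROT_C: OR 0.86 (0.66-1.13) p=2.89e-01 FDR=2.89e-01 cond_p=3.96e-01 [1 SNPs]
```

PROT_B's conditional p is NA: conditioning on a risk variant that *is* the
instrument leaves nothing to estimate — exactly how a trans pQTL
coinciding with a known disease locus is reported.  A thin CLI mirrors the
library (`pqtlmr simulate|harmonize|instruments|mr|condition|subtypes|report`).

## Layout

- `src/pqtlmr/` — `sumstats_io` (readers/writers, harmonization,
  meta-analysis), `ld_panel` (LD, pruning), `instruments` (per-protein
  instrument construction), `mr_engine` (IVW, OR/CI, FDR), `cojo`
  (conditional analysis), `simulate` (synthetic studies), `pipeline` +
  `cli` (orchestration), `published` (printed reference values).
- `docs/methods.md` — model, assumptions, numerical choices, limitations.
- `examples/` — runnable narrative scripts.
- `tests/` — unit, property, and acceptance suites.
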