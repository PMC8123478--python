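"""Harmonize two summary records and estimate a causal effect with IVW.

Builds a tiny two-SNP instrument for one protein, aligns the outcome
statistics to the exposure's effect alleles (note the second SNP's alleles
are swapped between the two sources), and reports the inverse-variance-
weighted causal estimate on the odds-ratio scale.
"""

from pqtlmr import (
    InstrumentSet,
    OutcomeRecord,
    PqtlRecord,
    harmonize,
    ivw_estimate,
    p_from_or_ci,
)

# exposure side: SNP effects on protein level, in SD per effect-allele copy
pqtls = [
    PqtlRecord("rs1001", "3", 49_000_000, "A", "G", 0.31, 0.42, 0.021,
               3e-82, "EXAMPLE_PROTEIN", "cis"),
    PqtlRecord("rs2002", "3", 52_000_000, "T", "C", 0.18, 0.35, 0.030,
               8e-28, "EXAMPLE_PROTEIN", "trans"),
]

# outcome side: SNP effects on disease, log-OR per effect-allele copy;
# rs2002 is reported for the opposite allele (C vs T)
outcome = [
    OutcomeRecord("rs1001", "3", 49_000_000, "A", "G", 0.30, 0.081, 0.018,
                  7e-6, 12906, 108979),
    OutcomeRecord("rs2002", "3", 52_000_000, "C", "T", 0.83, -0.064, 0.024,
                  7.7e-3, 12906, 108979),
]

snps = [harmonize(x, y) for x, y in zip(pqtls, outcome)]
for h in snps:
    print(f"{h.snp_id}: status={h.status.value} flip={h.flip_applied} "
          f"beta_gx={h.beta_gx:+.3f} beta_gy={h.beta_gy:+.3f}")

result = ivw_estimate(InstrumentSet("EXAMPLE_PROTEIN", snps=snps))
print(f"\nIVW log-OR per SD: {result.beta:.4f} (SE {result.se:.4f})")
print(f"OR (95% CI): {result.or_:.2f} ({result.ci_low:.2f}-{result.ci_high:.2f})")
print(f"p-value: {result.pval:.2e}")

# the printed OR/CI alone pin down the p-value (useful for auditing tables)
implied = p_from_or_ci(result.or_, result.ci_low, result.ci_high)
print(f"p implied by OR/CI: {implied:.2e}")

# Interpretation: each SD increase in genetically predicted protein level
# multiplies the odds of disease by the OR above; the flip on rs2002 shows
# why allele harmonization has to precede any pooling of SNP effects.
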