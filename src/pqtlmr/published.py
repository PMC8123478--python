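"""Reported summary values from a proteome-wide MR scan of endometrial cancer.

A published analysis of 1434 plasma proteins (pQTL instruments from a cohort
of 3562 individuals; outcome GWAS of 12,906 endometrial cancer cases and
108,979 controls) reported nine proteins associated with disease risk at
FDR < 0.05.  These printed numbers are self-contained inputs for
internal-consistency checks: the raw p-values of the nine top hits can be
re-adjusted as the smallest of 1434 tests, and each reported OR with its 95%
CI implies a p-value that should match the printed one.
"""

from __future__ import annotations

#: number of proteins tested in the proteome-wide scan
N_PROTEINS_TESTED = 1434

#: pQTL instrument significance threshold used by the source catalog
PQTL_P_THRESHOLD = 1.5e-11

#: raw p-values of the nine FDR-significant proteins, ascending
#: (VCAM-1, RA51D, Desmoglein-2, MICB, BGAT, intestinal alkaline
#: phosphatase, ST4S6, GLCE, DC-SIGN)
TOP_HIT_PVALUES = (
    1.14e-10,   # VCAM-1
    2.46e-8,    # RA51D
    2.18e-5,    # Desmoglein-2
    3.30e-5,    # MICB
    8.50e-5,    # BGAT
    1.84e-4,    # alkaline phosphatase, intestinal type
    1.84e-4,    # ST4S6
    2.14e-4,    # GLCE
    3.04e-4,    # DC-SIGN
)

TOP_HIT_PROTEINS = (
    "VCAM-1", "RA51D", "Desmoglein-2", "MICB", "BGAT",
    "Alkaline phosphatase intestine", "ST4S6", "GLCE", "DC-SIGN",
)

#: printed FDR-adjusted cells that are robust to rounding conventions:
#: rank 3 (Desmoglein-2) and rank 5 (BGAT), at 2-decimal precision
PRINTED_FDR_RANK3 = 0.01
PRINTED_FDR_RANK5 = 0.02

#: previously reported biomarker candidates that did not replicate:
#: protein -> (OR, CI lower, CI upper, printed p)
REPLICATION_CHECKS = {
    "DKK-1": (0.96, 0.87, 1.07, 0.44),
    "DJ-1": (0.94, 0.87, 1.03, 0.17),
    "GDF-15": (0.98, 0.93, 1.05, 0.59),
    "YKL-40": (1.00, 0.97, 1.03, 0.99),
    "IL-31": (0.95, 0.89, 1.02, 0.17),
}

#: GWAS-identified endometrial cancer risk variants used for conditioning
CONDITIONING_RSIDS = (
    "rs113998067", "rs148261157", "rs1679014", "rs10835920", "rs9668337",
    "rs3184504", "rs10850382", "rs1129506", "rs882380", "rs1740828",
    "rs2747716", "rs35286446", "rs4733613", "rs139584729", "rs7981863",
    "rs2498796", "rs937213", "rs17601876", "rs11263761",
)
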