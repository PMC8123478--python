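"""Per-protein instrument construction from a pQTL catalog.

For each protein: keep catalog rows at or below the pQTL significance
threshold, harmonize each against the outcome summary statistics, then
enforce independence by greedy LD pruning within each chromosome
(cross-chromosome pairs are independent by definition and are never pruned
against each other).  Proteins left with no usable SNP are reported as not
analyzable, never dropped silently.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .ld_panel import GenotypePanel, compute_ld, ld_prune
from .sumstats_io import harmonize
from .types import (
    HarmonizationStatus,
    HarmonizedInstrument,
    InstrumentSet,
    OutcomeRecord,
    PqtlRecord,
)

PQTL_P_THRESHOLD = 1.5e-11  # genome-wide pQTL significance used by the source catalog
R2_THRESHOLD = 0.1


@dataclass
class Diagnostic:
    """Why a SNP (or protein) left the analysis at a given stage."""

    protein_id: str
    snp_id: str
    stage: str
    reason: str


def build_instruments(catalog: Sequence[PqtlRecord],
                      outcome: Sequence[OutcomeRecord],
                      panel: Optional[GenotypePanel],
                      pqtl_p_threshold: float = PQTL_P_THRESHOLD,
                      r2_threshold: float = R2_THRESHOLD,
                      palindrome_eaf_window: float = 0.08,
                      ) -> tuple[list[InstrumentSet], list[Diagnostic]]:
    """Build pruned instrument sets for every protein in the catalog.

    SNPs absent from the outcome statistics are recorded with status
    ``missing_in_outcome`` (no proxy search is attempted).  SNPs absent from
    the LD panel are retained only when they are the sole candidate on their
    chromosome; otherwise pruning is impossible and they are excluded with a
    diagnostic (failing closed avoids correlated instruments).
    """
    if not catalog:
        raise ValueError("empty pQTL catalog")
    outcome_by_snp = {r.snp_id: r for r in outcome}
    by_protein: dict[str, list[PqtlRecord]] = defaultdict(list)
    for rec in catalog:
        by_protein[rec.protein_id].append(rec)

    sets: list[InstrumentSet] = []
    diags: list[Diagnostic] = []
    for protein_id in sorted(by_protein):
        records = _dedupe(by_protein[protein_id])
        iset = InstrumentSet(protein_id=protein_id)

        significant = []
        for rec in records:
            if rec.pval <= pqtl_p_threshold:
                significant.append(rec)
            else:
                diags.append(Diagnostic(protein_id, rec.snp_id, "threshold",
                                        f"pval {rec.pval:.3g} > {pqtl_p_threshold:.3g}"))

        harmonized: list[HarmonizedInstrument] = []
        pvals: dict[str, float] = {}
        for rec in significant:
            out = outcome_by_snp.get(rec.snp_id)
            if out is None:
                iset.missing_in_outcome.append(rec.snp_id)
                diags.append(Diagnostic(protein_id, rec.snp_id, "harmonize",
                                        "missing_in_outcome"))
                continue
            h = harmonize(rec, out, palindrome_eaf_window=palindrome_eaf_window)
            if h.status is not HarmonizationStatus.OK:
                iset.dropped.append(rec.snp_id)
                diags.append(Diagnostic(protein_id, rec.snp_id, "harmonize",
                                        h.status.value))
                continue
            harmonized.append(h)
            pvals[rec.snp_id] = rec.pval

        kept = _prune_within_chromosomes(
            protein_id, harmonized, pvals, panel, r2_threshold, iset, diags)
        iset.snps = kept
        if not kept:
            diags.append(Diagnostic(protein_id, "", "protein",
                                    "no analyzable instrument"))
        sets.append(iset)
    return sets, diags


def _dedupe(records: list[PqtlRecord]) -> list[PqtlRecord]:
    """Keep the smaller-p row when a SNP appears twice for one protein."""
    best: dict[str, PqtlRecord] = {}
    for rec in records:
        prev = best.get(rec.snp_id)
        if prev is None or rec.pval < prev.pval:
            best[rec.snp_id] = rec
    return [best[s] for s in sorted(best)]


def _prune_within_chromosomes(protein_id, harmonized, pvals, panel,
                              r2_threshold, iset, diags):
    by_chrom: dict[str, list[HarmonizedInstrument]] = defaultdict(list)
    for h in harmonized:
        by_chrom[h.chrom].append(h)
    kept: list[HarmonizedInstrument] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        if len(group) == 1:
            kept.extend(group)  # nothing to prune against, panel not needed
            continue
        in_panel = [h for h in group if panel is not None and h.snp_id in panel]
        for h in group:
            if panel is None or h.snp_id not in panel:
                iset.dropped.append(h.snp_id)
                diags.append(Diagnostic(
                    protein_id, h.snp_id, "prune",
                    "absent from LD panel with same-chromosome competitors"))
        if not in_panel:
            continue
        if len(in_panel) == 1:
            kept.extend(in_panel)
            continue
        ld = compute_ld(panel, [h.snp_id for h in in_panel])
        retained = set(ld_prune([(h.snp_id, pvals[h.snp_id]) for h in in_panel],
                                ld, r2_threshold=r2_threshold))
        for h in in_panel:
            if h.snp_id in retained:
                kept.append(h)
            else:
                iset.pruned_out.append(h.snp_id)
                diags.append(Diagnostic(protein_id, h.snp_id, "prune",
                                        f"r2 >= {r2_threshold} with a retained SNP"))
    kept.sort(key=lambda h: h.snp_id)
    return kept


MANIFEST_COLUMNS = ("protein", "snp", "chrom", "cis_trans",
                    "beta_gx", "beta_gy", "se_gy", "status")


def write_instruments_manifest(sets: Sequence[InstrumentSet],
                               path: str | Path) -> Path:
    """Delimited manifest of every instrument SNP and its fate."""
    rows = []
    for iset in sets:
        for h in iset.snps:
            rows.append((iset.protein_id, h.snp_id, h.chrom, h.cis_trans,
                         h.beta_gx, h.beta_gy, h.se_gy, "ok"))
        for snp in iset.pruned_out:
            rows.append((iset.protein_id, snp, "NA", "NA", "NA", "NA", "NA",
                         "pruned_out"))
        for snp in iset.missing_in_outcome:
            rows.append((iset.protein_id, snp, "NA", "NA", "NA", "NA", "NA",
                         "missing_in_outcome"))
        for snp in iset.dropped:
            rows.append((iset.protein_id, snp, "NA", "NA", "NA", "NA", "NA",
                         "dropped"))
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)
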