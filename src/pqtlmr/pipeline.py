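"""End-to-end orchestration: read, harmonize, instrument, estimate, adjust,
condition, and write result tables.

The flow mirrors a proteome-wide MR analysis: pQTL catalog and outcome GWAS
summary statistics in, one results row per protein (and per stratum for
subtype analyses) out.  Every SNP or protein that leaves the analysis is
accounted for with a reason code, so input SNP-protein pairs always equal
used pairs plus dropped pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import sumstats_io
from .cojo import conditional_estimates, conditional_mr
from .instruments import Diagnostic, build_instruments
from .ld_panel import GenotypePanel, read_panel
from .mr_engine import attach_fdr, ivw_estimate, p_from_or_ci
from .types import ConditioningSet, InstrumentSet, MrResult, Stratum

log = logging.getLogger("pqtlmr")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    catalog: Path
    outcome: Mapping[str, Path]            # stratum name -> summary file
    panel_dosages: Optional[Path] = None
    panel_variants: Optional[Path] = None
    conditioning: Optional[Path] = None
    out_dir: Path = Path("results")
    pqtl_p_threshold: float = 1.5e-11
    r2_threshold: float = 0.1
    fdr_alpha: float = 0.05
    alpha: float = 0.05
    m_total: Optional[int] = None
    palindrome_eaf_window: float = 0.08
    condition_all: bool = False            # condition every protein, not just FDR hits
    column_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        self.catalog = Path(self.catalog)
        self.outcome = {k: Path(v) for k, v in self.outcome.items()}
        self.out_dir = Path(self.out_dir)
        if not (0 < self.fdr_alpha < 1 and 0 < self.alpha < 1):
            raise ValueError("alpha levels must be in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if not (0 < self.pqtl_p_threshold <= 1):
            raise ValueError("pqtl_p_threshold must be in (0, 1]")


@dataclass
class PipelineReport:
    """Results plus full accounting of what happened to every input pair."""

    results: list[MrResult] = field(default_factory=list)
    instrument_sets: list[InstrumentSet] = field(default_factory=list)
    diagnostics: list[Diagnostic] = field(default_factory=list)
    n_input_pairs: int = 0
    table_path: Optional[Path] = None

    @property
    def n_used(self) -> int:
        return sum(len(s.snps) for s in self.instrument_sets)

    @property
    def n_dropped(self) -> int:
        return sum(len(s.pruned_out) + len(s.missing_in_outcome) + len(s.dropped)
                   for s in self.instrument_sets) + self._n_threshold_dropped

    @property
    def _n_threshold_dropped(self) -> int:
        return sum(1 for d in self.diagnostics if d.stage == "threshold")


def _load_panel(config: RunConfig) -> Optional[GenotypePanel]:
    if config.panel_dosages is None or config.panel_variants is None:
        return None
    return read_panel(config.panel_dosages, config.panel_variants)


def run_overall(config: RunConfig) -> PipelineReport:
    """The main analysis: IVW per protein, BH-FDR across the panel, then
    conditional re-estimation on known risk variants for FDR-significant
    proteins (configurable to all)."""
    log.info("[read] catalog %s", config.catalog)
    catalog_report = sumstats_io.read_pqtl_catalog(config.catalog,
                                                   config.column_map)
    if not catalog_report.records:
        raise ValueError(f"empty pQTL catalog: {config.catalog}")
    for issue in catalog_report.rejects:
        log.warning("[read] catalog reject %s", issue)

    overall_path = config.outcome.get(Stratum.OVERALL.value)
    if overall_path is None:
        raise ValueError("config.outcome must provide an 'overall' file")
    outcome_report = sumstats_io.read_outcome_stats(
        overall_path, config.column_map, stratum=Stratum.OVERALL)
    panel = _load_panel(config)

    log.info("[instruments] %d catalog records, %d outcome SNPs",
             len(catalog_report.records), len(outcome_report.records))
    sets, diags = build_instruments(
        catalog_report.records, outcome_report.records, panel,
        pqtl_p_threshold=config.pqtl_p_threshold,
        r2_threshold=config.r2_threshold,
        palindrome_eaf_window=config.palindrome_eaf_window)
    for d in diags:
        log.info("[instruments] %s %s %s: %s", d.protein_id, d.snp_id,
                 d.stage, d.reason)

    results = [ivw_estimate(s) for s in sets]
    m_total = config.m_total or sum(1 for r in results if not r.is_na)
    attach_fdr(results, m_total=m_total)
    log.info("[mr] %d proteins estimated, m_total=%d", len(results), m_total)

    if config.conditioning is not None and panel is not None:
        _run_conditional(config, panel, sets, results,
                         outcome_report.records)

    report = PipelineReport(
        results=results, instrument_sets=sets, diagnostics=diags,
        n_input_pairs=len(catalog_report.records))
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report.table_path = sumstats_io.write_results_table(
        results, config.out_dir / "mr_results_overall.tsv")
    log.info("[write] %s (used %d, dropped %d of %d pairs)",
             report.table_path, report.n_used, report.n_dropped,
             report.n_input_pairs)
    return report


def _run_conditional(config, panel, sets, results, outcome_records) -> None:
    conditioning = sumstats_io.read_conditioning_list(config.conditioning)
    outcome_by_snp = {r.snp_id: r for r in outcome_records}
    cond_records = [outcome_by_snp[s] for s in conditioning.snp_ids
                    if s in outcome_by_snp]
    missing = [s for s in conditioning.snp_ids if s not in outcome_by_snp
               or s not in panel]
    if missing:
        log.warning("[condition] conditioning SNPs unavailable, skipped: %s",
                    missing)
    cond_records = [r for r in cond_records if r.snp_id in panel]
    by_protein = {s.protein_id: s for s in sets}
    for res in results:
        if res.is_na:
            continue
        if not config.condition_all and (res.fdr_p is None
                                         or res.fdr_p >= config.fdr_alpha):
            continue
        iset = by_protein[res.protein_id]
        if any(s in conditioning for s in iset.snp_ids):
            res.cond_pval = None  # instrument itself is a known risk variant
            log.info("[condition] %s: instrument in conditioning set -> NA",
                     res.protein_id)
            continue
        targets = [outcome_by_snp[s] for s in iset.snp_ids]
        cond = conditional_estimates(targets, cond_records, panel)
        cmr = conditional_mr(iset, cond, conditioning)
        res.cond_pval = None if cmr.is_na else cmr.pval
        log.info("[condition] %s: conditional p=%s", res.protein_id,
                 res.cond_pval)


def run_subtypes(config: RunConfig) -> dict[str, PipelineReport]:
    """Per-stratum analyses with the overall instrument definitions.

    An instrument SNP missing from a stratum's summary file is dropped from
    that stratum's set; a protein whose entire instrument is missing yields
    an NA row for that stratum only.  Subtype results report raw p-values
    (no per-stratum FDR).
    """
    catalog_report = sumstats_io.read_pqtl_catalog(config.catalog,
                                                   config.column_map)
    if not catalog_report.records:
        raise ValueError(f"empty pQTL catalog: {config.catalog}")
    panel = _load_panel(config)
    reports: dict[str, PipelineReport] = {}
    for stratum_name, path in config.outcome.items():
        stratum = Stratum(stratum_name)
        if stratum is Stratum.OVERALL:
            continue
        outcome_report = sumstats_io.read_outcome_stats(
            path, config.column_map, stratum=stratum)
        sets, diags = build_instruments(
            catalog_report.records, outcome_report.records, panel,
            pqtl_p_threshold=config.pqtl_p_threshold,
            r2_threshold=config.r2_threshold,
            palindrome_eaf_window=config.palindrome_eaf_window)
        results = [ivw_estimate(s, stratum=stratum) for s in sets]
        report = PipelineReport(results=results, instrument_sets=sets,
                                diagnostics=diags,
                                n_input_pairs=len(catalog_report.records))
        config.out_dir.mkdir(parents=True, exist_ok=True)
        report.table_path = sumstats_io.write_results_table(
            results, config.out_dir / f"mr_results_{stratum.value}.tsv")
        log.info("[subtypes] %s -> %s", stratum.value, report.table_path)
        reports[stratum.value] = report
    return reports


def consistency_report(results: pd.DataFrame | str | Path,
                       flag_factor: float = 2.0) -> pd.DataFrame:
    """Check each results row's printed OR/CI against its printed p-value.

    Recomputes the p-value implied by the (printed-precision) OR and CI and
    flags rows where printed and implied p differ by more than
    ``flag_factor``-fold — a rounding guard, since both numbers are printed
    at limited precision.
    """
    if not isinstance(results, pd.DataFrame):
        results = sumstats_io.read_results_table(results)
    rows = []
    for _, row in results.iterrows():
        entry = {"protein": row.get("protein"), "implied_p": None,
                 "printed_p": row.get("pval"), "consistent": None}
        try:
            or_, lo, hi = float(row["or"]), float(row["ci_low"]), float(row["ci_high"])
            printed_p = float(row["pval"])
        except (TypeError, ValueError):
            rows.append(entry)  # NA row: nothing to check
            continue
        implied = p_from_or_ci(or_, lo, hi)
        entry["implied_p"] = implied
        hi_p, lo_p = max(implied, printed_p), min(implied, printed_p)
        entry["consistent"] = bool(lo_p > 0 and hi_p / lo_p <= flag_factor)
        rows.append(entry)
    return pd.DataFrame(rows)
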