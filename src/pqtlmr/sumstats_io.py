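"""Readers, writers, harmonization and meta-analysis for summary-statistics tables.

File dialect: tab-delimited UTF-8 with a mandatory header; missing values are
encoded ``NA``.  Column names are resolved through a user-supplied column map
so that readers stay agnostic to the many circulating GWAS summary formats.
Rows violating type invariants are rejected with a line-numbered reason and
never silently coerced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    HarmonizationStatus,
    HarmonizedInstrument,
    MrResult,
    OutcomeRecord,
    PqtlRecord,
    Stratum,
    is_palindromic,
)

PQTL_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta_gx",
    "se_gx",
    "pval",
    "protein_id",
    "cis_trans",
)

OUTCOME_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta_gy",
    "se_gy",
    "pval",
    "n_cases",
    "n_controls",
)

#: relative tolerance for the p-value vs |beta/se| consistency warning
PVAL_Z_REL_TOL = 0.10


@dataclass
class RowIssue:
    """A line-numbered problem found while reading a table (line 1 = header)."""

    line: int
    reason: str
    snp_id: Optional[str] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        snp = f" [{self.snp_id}]" if self.snp_id else ""
        return f"line {self.line}{snp}: {self.reason}"


@dataclass
class ReadReport:
    """Parsed records plus per-row rejects and warnings."""

    records: list = field(default_factory=list)
    rejects: list[RowIssue] = field(default_factory=list)
    warnings: list[RowIssue] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)


def _read_table(path: str | Path, column_map: Optional[Mapping[str, str]],
                required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {column_map.get(k, k): k for k in required}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"available: {list(df.columns)}"
        )
    return df.rename(columns=rename)


def read_pqtl_catalog(path: str | Path,
                      column_map: Optional[Mapping[str, str]] = None) -> ReadReport:
    """Read a pQTL catalog (one row per SNP-protein association).

    Duplicate (snp_id, protein_id) pairs are resolved deterministically: the
    row with the smaller p-value is kept and the others are rejected with a
    ``duplicate`` reason.
    """
    df = _read_table(path, column_map, PQTL_FIELDS)
    report = ReadReport()
    best: dict[tuple[str, str], tuple[float, int]] = {}  # key -> (pval, idx in records)
    lines: list[int] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            rec = PqtlRecord(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                eaf=float(row["eaf"]),
                beta_gx=float(row["beta_gx"]),
                se_gx=float(row["se_gx"]),
                pval=float(row["pval"]),
                protein_id=str(row["protein_id"]),
                cis_trans=str(row["cis_trans"]).lower(),
            )
        except (ValueError, TypeError) as exc:
            report.rejects.append(RowIssue(line, str(exc), row.get("snp_id")))
            continue
        key = (rec.snp_id, rec.protein_id)
        if key in best:
            prev_pval, prev_i = best[key]
            if rec.pval < prev_pval:
                report.rejects.append(RowIssue(
                    lines[prev_i], f"duplicate (snp_id, protein_id) {key}; "
                    "kept smaller-p row", rec.snp_id))
                report.records[prev_i] = rec
                lines[prev_i] = line
                best[key] = (rec.pval, prev_i)
            else:
                report.rejects.append(RowIssue(
                    line, f"duplicate (snp_id, protein_id) {key}; "
                    "kept smaller-p row", rec.snp_id))
        else:
            best[key] = (rec.pval, len(report.records))
            report.records.append(rec)
            lines.append(line)
    return report


def read_outcome_stats(path: str | Path,
                       column_map: Optional[Mapping[str, str]] = None,
                       stratum: Stratum | str = Stratum.OVERALL) -> ReadReport:
    """Read outcome GWAS summary statistics for one stratum, keyed on snp_id.

    A p-value inconsistent with ``2*(1-Phi(|beta/se|))`` beyond 10% relative
    difference keeps the row but emits a warning (published p-values are
    rounded, so this is diagnostic, not fatal).
    """
    stratum = Stratum(stratum)
    df = _read_table(path, column_map, OUTCOME_FIELDS)
    report = ReadReport()
    seen: dict[str, int] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            rec = OutcomeRecord(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                eaf=float(row["eaf"]),
                beta_gy=float(row["beta_gy"]),
                se_gy=float(row["se_gy"]),
                pval=float(row["pval"]),
                n_cases=int(row["n_cases"]),
                n_controls=int(row["n_controls"]),
                stratum=stratum,
            )
        except (ValueError, TypeError) as exc:
            report.rejects.append(RowIssue(line, str(exc), row.get("snp_id")))
            continue
        if rec.snp_id in seen:
            report.rejects.append(RowIssue(
                line, f"duplicate snp_id {rec.snp_id} within stratum", rec.snp_id))
            continue
        p_from_z = 2.0 * stats.norm.sf(abs(rec.beta_gy / rec.se_gy))
        if p_from_z > 0 and abs(p_from_z - rec.pval) / p_from_z > PVAL_Z_REL_TOL:
            msg = (f"pval {rec.pval:.3g} inconsistent with beta/se "
                   f"(implies {p_from_z:.3g})")
            report.warnings.append(RowIssue(line, msg, rec.snp_id))
            warnings.warn(f"{path}: line {line}: {msg}", stacklevel=2)
        seen[rec.snp_id] = line
        report.records.append(rec)
    return report


def write_pqtl_catalog(records: Iterable[PqtlRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [{f: getattr(r, f) for f in PQTL_FIELDS} for r in records]
    df = pd.DataFrame(rows, columns=list(PQTL_FIELDS))
    # default float formatting is shortest-round-trip: re-reading is lossless
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def write_outcome_stats(records: Iterable[OutcomeRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [{f: getattr(r, f) for f in OUTCOME_FIELDS} for r in records]
    df = pd.DataFrame(rows, columns=list(OUTCOME_FIELDS))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def harmonize(x: PqtlRecord, y: OutcomeRecord,
              palindrome_eaf_window: float = 0.08) -> HarmonizedInstrument:
    """Align an outcome record's alleles to a pQTL record's effect allele.

    Rules (conservative standard practice; no strand inference is attempted):

    * identical (effect, other) pairs: signs unchanged;
    * swapped pairs: the outcome beta's sign is flipped and its EAF complemented;
    * palindromic SNPs (A/T, C/G) whose minor-allele frequency lies within
      ``palindrome_eaf_window`` of 0.5 in either source are dropped as
      strand-ambiguous;
    * any other allele configuration is dropped as a mismatch.
    """
    if x.snp_id != y.snp_id:
        raise ValueError(f"snp_id mismatch: {x.snp_id} vs {y.snp_id}")

    def drop(status: HarmonizationStatus) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            snp_id=x.snp_id, beta_gx=x.beta_gx, se_gx=x.se_gx,
            beta_gy=math.nan, se_gy=math.nan, flip_applied=False,
            status=status, chrom=x.chrom, cis_trans=x.cis_trans)

    if {x.effect_allele, x.other_allele} != {y.effect_allele, y.other_allele}:
        return drop(HarmonizationStatus.DROPPED_ALLELE_MISMATCH)

    if is_palindromic(x.effect_allele, x.other_allele):
        for eaf in (x.eaf, y.eaf):
            maf = min(eaf, 1.0 - eaf)
            if 0.5 - maf <= palindrome_eaf_window:
                return drop(HarmonizationStatus.DROPPED_PALINDROMIC)

    if (y.effect_allele, y.other_allele) == (x.effect_allele, x.other_allele):
        beta_gy, flip = y.beta_gy, False
    else:  # swapped coding
        beta_gy, flip = -y.beta_gy, True

    return HarmonizedInstrument(
        snp_id=x.snp_id, beta_gx=x.beta_gx, se_gx=x.se_gx,
        beta_gy=beta_gy, se_gy=y.se_gy, flip_applied=flip,
        status=HarmonizationStatus.OK, chrom=x.chrom, cis_trans=x.cis_trans)


def fixed_effects_meta(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Fixed-effects inverse-variance-weighted meta-analysis of per-study estimates.

    Returns the pooled ``(beta, se)`` with weights ``w_i = se_i**-2``:
    ``beta = sum(w_i * b_i) / sum(w_i)`` and ``se = sum(w_i)**-0.5``.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("fixed_effects_meta requires at least one study")
    if betas.shape != ses.shape:
        raise ValueError("betas and ses must have equal length")
    if not np.all(ses > 0):
        raise ValueError("all standard errors must be > 0")
    w = ses ** -2.0
    return float(np.sum(w * betas) / np.sum(w)), float(np.sum(w) ** -0.5)


RESULT_COLUMNS = (
    "protein", "gene", "region", "instruments", "type_of_pqtl", "n_snps",
    "or", "ci_low", "ci_high", "pval", "fdr_pval", "cond_pval", "stratum",
)


def write_results_table(results: Sequence[MrResult], path: str | Path,
                        protein_info: Optional[Mapping[str, Mapping[str, str]]] = None
                        ) -> Path:
    """Write per-protein MR results as a tab-delimited table.

    OR and CI bounds are printed at 2 decimals and p-values in scientific
    notation, matching the precision conventions of published MR result
    tables.  ``protein_info`` may supply ``gene``/``region`` annotations per
    protein id.
    """
    protein_info = protein_info or {}
    rows = []
    for r in results:
        info = protein_info.get(r.protein_id, {})
        if r.is_na:
            or_ = lo = hi = p = fdr = cond = "NA"
        else:
            or_, lo, hi = f"{r.or_:.2f}", f"{r.ci_low:.2f}", f"{r.ci_high:.2f}"
            p = f"{r.pval:.2e}"
            fdr = "NA" if r.fdr_p is None else f"{r.fdr_p:.2e}"
            cond = "NA" if r.cond_pval is None else f"{r.cond_pval:.2e}"
        rows.append({
            "protein": r.protein_id,
            "gene": info.get("gene", "NA"),
            "region": info.get("region", "NA"),
            "instruments": "; ".join(r.instrument_snps) or "NA",
            "type_of_pqtl": r.cis_trans or "NA",
            "n_snps": r.n_snps,
            "or": or_, "ci_low": lo, "ci_high": hi,
            "pval": p, "fdr_pval": fdr, "cond_pval": cond,
            "stratum": Stratum(r.stratum).value,
        })
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def read_conditioning_list(path: str | Path, source: str = "") -> "ConditioningSet":
    """Read a plain-text conditioning list, one rsID per line (# comments allowed)."""
    from .types import ConditioningSet

    ids = []
    for raw in Path(path).read_text().splitlines():
        token = raw.strip()
        if token and not token.startswith("#"):
            ids.append(token)
    return ConditioningSet(snp_ids=tuple(ids), source=source or str(path))
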