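"""Reference-panel LD computation and greedy independence pruning.

The panel is a dosage matrix (individuals x variants, entries in [0, 2])
with a variant map; r is the Pearson correlation of dosage columns (allelic
correlation), and r**2 is the LD measure used for pruning.  Missing dosages
are mean-imputed per column before correlating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele")


@dataclass
class GenotypePanel:
    """Reference genotypes for LD estimation (e.g. a 1000-Genomes-like panel)."""

    dosages: np.ndarray                 # (n_individuals, n_variants)
    variants: pd.DataFrame              # columns VARIANT_COLUMNS
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant map length does not match dosage columns")
        ids = list(self.variants["snp_id"])
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self._index = {s: i for i, s in enumerate(ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.variants["snp_id"])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP, missing values mean-imputed."""
        try:
            col = self.dosages[:, self._index[snp_id]]
        except KeyError:
            raise KeyError(f"SNP {snp_id} not in panel") from None
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        return col

    def variant(self, snp_id: str) -> pd.Series:
        return self.variants.iloc[self._index[snp_id]]

    def frequency(self, snp_id: str) -> float:
        """Effect-allele frequency implied by mean dosage."""
        return float(np.nanmean(self.dosages[:, self._index[snp_id]]) / 2.0)


@dataclass
class LdMatrix:
    """Pairwise Pearson correlations among a set of SNPs (diagonal exactly 1)."""

    snp_ids: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        np.fill_diagonal(self.r, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r_of(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r_of(a, b) ** 2

    @property
    def r_squared(self) -> np.ndarray:
        return self.r ** 2


def compute_ld(panel: GenotypePanel, snp_ids: Sequence[str]) -> LdMatrix:
    """Pairwise dosage correlations for the requested SNPs.

    Raises ``ValueError`` naming the SNP if any requested column is constant
    (its correlation would be undefined).
    """
    cols = np.column_stack([panel.column(s) for s in snp_ids])
    sds = cols.std(axis=0)
    for snp, sd in zip(snp_ids, sds):
        if sd == 0:
            raise ValueError(f"constant dosage column for SNP {snp}; LD undefined")
    if len(snp_ids) == 1:
        r = np.ones((1, 1))
    else:
        r = np.corrcoef(cols, rowvar=False)
    return LdMatrix(snp_ids=list(snp_ids), r=r)


def ld_prune(candidates: Sequence[tuple[str, float]], ld: LdMatrix,
             r2_threshold: float = 0.1) -> list[str]:
    """Greedy p-value-ranked clumping to a pairwise-independent SNP set.

    Candidates are sorted by ascending p-value (ties broken lexicographically
    by snp_id); the best remaining SNP is kept and every remaining SNP with
    r**2 >= ``r2_threshold`` against it is discarded.  The retained set is
    therefore pairwise r**2 < threshold, and the output is invariant to the
    input order of ``candidates``.
    """
    for snp, _ in candidates:
        if snp not in ld:
            raise KeyError(f"candidate SNP {snp} missing from LD matrix")
    queue = sorted(candidates, key=lambda c: (c[1], c[0]))
    kept: list[str] = []
    while queue:
        best, _ = queue.pop(0)
        kept.append(best)
        queue = [(s, p) for s, p in queue if ld.r2(best, s) < r2_threshold]
    return kept


def write_panel(panel: GenotypePanel, dosage_path: str | Path,
                variant_path: str | Path) -> None:
    """Write a panel as two tab-delimited files (dosages; variant map)."""
    pd.DataFrame(panel.dosages, columns=panel.snp_ids).to_csv(
        dosage_path, sep="\t", index=False, float_format="%.6g")
    panel.variants.to_csv(variant_path, sep="\t", index=False)


def read_panel(dosage_path: str | Path, variant_path: str | Path) -> GenotypePanel:
    variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    missing = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing:
        raise ValueError(f"variant map missing columns {sorted(missing)}")
    dosages = pd.read_csv(dosage_path, sep="\t")
    if list(dosages.columns) != list(variants["snp_id"]):
        raise ValueError("dosage columns do not match variant map order")
    return GenotypePanel(dosages=dosages.to_numpy(dtype=float), variants=variants)


def panel_from_vcf(path: str | Path,
                   snp_ids: Optional[Sequence[str]] = None) -> GenotypePanel:
    """Extract a dosage panel from a VCF (DS field if present, else GT counts).

    Restricted to the requested SNP ids when given.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    wanted = set(snp_ids) if snp_ids is not None else None
    cols, rows = [], []
    for var in VCF(str(path)):
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if wanted is not None and vid not in wanted:
            continue
        if len(var.ALT) != 1:
            continue  # multi-allelic splitting is out of scope
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).ravel()
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            dose = np.where((gts < 0).any(axis=1), np.nan,
                            gts.clip(min=0).sum(axis=1)).astype(float)
        cols.append(dose)
        rows.append({"snp_id": vid, "chrom": var.CHROM, "pos": var.POS,
                     "effect_allele": var.ALT[0], "other_allele": var.REF})
    if not cols:
        raise ValueError(f"no usable variants read from {path}")
    return GenotypePanel(dosages=np.column_stack(cols),
                         variants=pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)))
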