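"""Core record types exchanged between pipeline stages.

All effect sizes follow GWAS summary-statistic conventions: the exposure
(protein) effect ``beta_gx`` is expressed in protein standard deviations per
copy of the effect allele, and the outcome effect ``beta_gy`` is a log odds
ratio per copy of the effect allele.  Positions are 1-based; chromosome
labels are stored without a leading ``chr``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

_VALID_BASES = frozenset("ACGT")

#: complementary base pairs that make a SNP strand-ambiguous
_PALINDROMIC_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class Stratum(str, enum.Enum):
    """Outcome analysis stratum (disease overall or a histologic subtype)."""

    OVERALL = "overall"
    ENDOMETRIOID = "endometrioid"
    NON_ENDOMETRIOID = "non_endometrioid"


class HarmonizationStatus(str, enum.Enum):
    OK = "ok"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_ALLELE_MISMATCH = "dropped_allele_mismatch"
    MISSING_IN_OUTCOME = "missing_in_outcome"


def _check_alleles(effect_allele: str, other_allele: str) -> None:
    if not effect_allele or not other_allele:
        raise ValueError("alleles must be non-empty")
    if effect_allele == other_allele:
        raise ValueError(f"effect and other allele identical: {effect_allele}")
    for allele in (effect_allele, other_allele):
        if not set(allele) <= _VALID_BASES:
            raise ValueError(f"allele {allele!r} contains non-ACGT characters")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be resolved from alleles."""
    return frozenset({effect_allele, other_allele}) in _PALINDROMIC_PAIRS


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True)
class PqtlRecord:
    """One SNP-protein association from a pQTL catalog."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_gx: float
    se_gx: float
    pval: float
    protein_id: str
    cis_trans: str  # "cis" or "trans"

    def __post_init__(self) -> None:
        _check_alleles(self.effect_allele, self.other_allele)
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")
        if not self.se_gx > 0:
            raise ValueError(f"se_gx must be > 0, got {self.se_gx}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"pval must be in (0,1], got {self.pval}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.cis_trans not in ("cis", "trans"):
            raise ValueError(f"cis_trans must be 'cis' or 'trans', got {self.cis_trans!r}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class OutcomeRecord:
    """One SNP-disease association from a case-control GWAS, on the log-OR scale.

    For continuous-trait summary statistics (used by the conditional-analysis
    machinery on simulated quantitative phenotypes) set ``n_controls = 0`` and
    put the total sample size in ``n_cases``.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_gy: float
    se_gy: float
    pval: float
    n_cases: int
    n_controls: int
    stratum: Stratum = Stratum.OVERALL

    def __post_init__(self) -> None:
        _check_alleles(self.effect_allele, self.other_allele)
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")
        if not self.se_gy > 0:
            raise ValueError(f"se_gy must be > 0, got {self.se_gy}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"pval must be in (0,1], got {self.pval}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("case/control counts must be non-negative")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "stratum", Stratum(self.stratum))

    @property
    def n_effective(self) -> float:
        """Effective sample size: 4/(1/cases + 1/controls), or n for continuous traits."""
        if self.n_controls == 0:
            return float(self.n_cases)
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An allele-aligned SNP carrying the per-SNP triple entering the IVW sums."""

    snp_id: str
    beta_gx: float
    se_gx: float
    beta_gy: float
    se_gy: float
    flip_applied: bool
    status: HarmonizationStatus
    chrom: str = ""
    cis_trans: str = ""

    @property
    def ok(self) -> bool:
        return self.status is HarmonizationStatus.OK


@dataclass
class InstrumentSet:
    """Pruned, harmonized instrument SNPs for one protein."""

    protein_id: str
    snps: list[HarmonizedInstrument] = field(default_factory=list)
    pruned_out: list[str] = field(default_factory=list)
    missing_in_outcome: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def n_cis(self) -> int:
        return sum(1 for s in self.snps if s.cis_trans == "cis")

    @property
    def n_trans(self) -> int:
        return sum(1 for s in self.snps if s.cis_trans == "trans")

    @property
    def analyzable(self) -> bool:
        return len(self.snps) > 0

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


@dataclass
class MrResult:
    """Per-protein causal estimate: log-OR per SD of genetically predicted protein."""

    protein_id: str
    stratum: Stratum = Stratum.OVERALL
    beta: float = math.nan
    se: float = math.nan
    pval: float = math.nan
    or_: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    fdr_p: Optional[float] = None
    cond_pval: Optional[float] = None
    n_snps: int = 0
    is_na: bool = False
    instrument_snps: list[str] = field(default_factory=list)
    cis_trans: str = ""


@dataclass
class ConditionalRecord:
    """One SNP's association with disease after conditioning on a SNP set."""

    snp_id: str
    beta_cond: float = math.nan
    se_cond: float = math.nan
    pval_cond: float = math.nan
    dropped_collinear: bool = False
    dropped_freq_mismatch: bool = False

    @property
    def usable(self) -> bool:
        return not (self.dropped_collinear or self.dropped_freq_mismatch)


@dataclass(frozen=True)
class ConditioningSet:
    """Known risk variants to condition on (e.g. GWAS-identified disease loci)."""

    snp_ids: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("conditioning SNP ids must be unique")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.snp_ids

    def __len__(self) -> int:
        return len(self.snp_ids)
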