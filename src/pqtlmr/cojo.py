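"""Approximate conditional association analysis from summary statistics.

Reconstructs individual-level regression from marginal GWAS estimates, a
reference LD panel, allele frequencies and per-SNP effective sample sizes,
following the standard summary-statistic conditional-analysis construction:
the (scaled) genotype cross-product between SNPs k and l is approximated by
``r_kl * sqrt(D_k * D_l)`` with ``D_k = 2 p_k (1 - p_k) n_k``, so joint
coefficients of a conditioning set follow from its normal equations and a
target's conditional effect is its joint coefficient in the model
{target + conditioning set}.  Case-control log-ORs are treated as linear
phenotype effects with effective sample size ``4/(1/cases + 1/controls)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ld_panel import GenotypePanel, compute_ld
from .mr_engine import ivw_estimate
from .types import (
    ConditionalRecord,
    ConditioningSet,
    InstrumentSet,
    MrResult,
    OutcomeRecord,
    Stratum,
)

COLLINEARITY_R2 = 0.9
FREQ_DIFF_THRESHOLD = 0.2
_COND_NUMBER_LIMIT = 1e12


@dataclass
class _Aligned:
    """Summary record re-expressed on the panel's effect-allele coding."""

    record: OutcomeRecord
    beta: float
    eaf: float
    flipped: bool
    freq_mismatch: bool

    @property
    def d(self) -> float:
        """Approximate genotype sum of squares 2p(1-p)n_eff."""
        return 2.0 * self.eaf * (1.0 - self.eaf) * self.record.n_effective


def _align_to_panel(rec: OutcomeRecord, panel: GenotypePanel,
                    freq_diff_threshold: float) -> _Aligned:
    var = panel.variant(rec.snp_id)
    if (rec.effect_allele, rec.other_allele) == (var["effect_allele"],
                                                 var["other_allele"]):
        beta, eaf, flipped = rec.beta_gy, rec.eaf, False
    elif (rec.effect_allele, rec.other_allele) == (var["other_allele"],
                                                   var["effect_allele"]):
        beta, eaf, flipped = -rec.beta_gy, 1.0 - rec.eaf, True
    else:
        raise ValueError(
            f"{rec.snp_id}: alleles {rec.effect_allele}/{rec.other_allele} "
            f"do not match panel {var['effect_allele']}/{var['other_allele']}")
    mismatch = abs(panel.frequency(rec.snp_id) - eaf) > freq_diff_threshold
    return _Aligned(rec, beta, eaf, flipped, mismatch)


def _phenotypic_ss(aligned: Sequence[_Aligned]) -> float:
    """Median-based estimate of the phenotype sum of squares n*var(y).

    From each marginal regression, Syy = D_k * (b_k^2 + (n_k - 2) * se_k^2);
    the median over SNPs is robust to the occasional outlying summary row.
    """
    vals = [a.d * (a.beta ** 2 + (a.record.n_effective - 2) * a.record.se_gy ** 2)
            for a in aligned]
    return float(np.median(vals))


def conditional_estimates(targets: Sequence[OutcomeRecord],
                          conditioning: Sequence[OutcomeRecord],
                          panel: GenotypePanel,
                          collinearity_r2: float = COLLINEARITY_R2,
                          freq_diff_threshold: float = FREQ_DIFF_THRESHOLD,
                          ) -> list[ConditionalRecord]:
    """Conditional effect of each target SNP given the conditioning set.

    With an empty conditioning set this is the identity (marginal estimates
    pass through unchanged).  Targets with r**2 >= ``collinearity_r2``
    against any conditioning SNP are flagged ``dropped_collinear`` rather
    than estimated; a target whose panel allele frequency disagrees with its
    summary frequency by more than ``freq_diff_threshold`` is flagged
    ``dropped_freq_mismatch``.  Reported betas keep each target record's
    original effect-allele orientation.
    """
    if not conditioning:
        return [ConditionalRecord(snp_id=t.snp_id, beta_cond=t.beta_gy,
                                  se_cond=t.se_gy, pval_cond=t.pval)
                for t in targets]

    for rec in list(targets) + list(conditioning):
        if rec.snp_id not in panel:
            raise KeyError(f"SNP {rec.snp_id} required for conditioning is "
                           "absent from the reference panel")

    cond = [_align_to_panel(r, panel, freq_diff_threshold) for r in conditioning]
    targ = [_align_to_panel(r, panel, freq_diff_threshold) for r in targets]
    cond_ids = [a.record.snp_id for a in cond]
    all_ids = cond_ids + [a.record.snp_id for a in targ
                          if a.record.snp_id not in set(cond_ids)]
    ld = compute_ld(panel, all_ids)

    d_c = np.array([a.d for a in cond])
    r_cc = np.array([[ld.r_of(a, b) for b in cond_ids] for a in cond_ids])
    b_cc = r_cc * np.sqrt(np.outer(d_c, d_c))
    if np.linalg.cond(b_cc) > _COND_NUMBER_LIMIT:
        raise np.linalg.LinAlgError(
            f"singular conditioning LD block: {cond_ids}")
    syy = _phenotypic_ss(cond + targ)

    out: list[ConditionalRecord] = []
    for a in targ:
        snp = a.record.snp_id
        if a.freq_mismatch:
            out.append(ConditionalRecord(snp_id=snp, dropped_freq_mismatch=True))
            continue
        r_tc = np.array([ld.r_of(snp, c) for c in cond_ids])
        if np.max(r_tc ** 2) >= collinearity_r2:
            out.append(ConditionalRecord(snp_id=snp, dropped_collinear=True))
            continue
        # joint model of {target, conditioning set}
        d_t = a.d
        w = r_tc * np.sqrt(d_t * d_c)          # X_t' X_C
        b_full = np.empty((1 + len(cond), 1 + len(cond)))
        b_full[0, 0] = d_t
        b_full[0, 1:] = w
        b_full[1:, 0] = w
        b_full[1:, 1:] = b_cc
        rhs = np.concatenate([[d_t * a.beta], d_c * np.array([c.beta for c in cond])])
        coef = np.linalg.solve(b_full, rhs)
        n_eff = a.record.n_effective
        dof = max(n_eff - len(coef) - 1, 1.0)
        sigma2 = (syy - float(coef @ rhs)) / dof
        sigma2 = max(sigma2, 1e-12)             # guard against approximation error
        x_mx = d_t - float(w @ np.linalg.solve(b_cc, w))  # x_t' M_C x_t
        if x_mx <= 0:
            out.append(ConditionalRecord(snp_id=snp, dropped_collinear=True))
            continue
        beta_cond = float(coef[0])
        se_cond = math.sqrt(sigma2 / x_mx)
        if a.flipped:
            beta_cond = -beta_cond
        pval = float(min(1.0, 2.0 * stats.norm.sf(abs(beta_cond / se_cond))))
        out.append(ConditionalRecord(snp_id=snp, beta_cond=beta_cond,
                                     se_cond=se_cond, pval_cond=pval))
    return out


def conditional_mr(instr: InstrumentSet,
                   cond: Sequence[ConditionalRecord],
                   conditioning: Optional[ConditioningSet] = None,
                   stratum: Stratum | str = Stratum.OVERALL) -> MrResult:
    """Re-estimate a protein's IVW effect using conditional outcome statistics.

    An instrument SNP that is itself a known risk variant (a member of the
    conditioning set) makes the conditional estimate undefined, so the result
    is NA.  Otherwise each instrument's (beta_gy, se_gy) is replaced by its
    conditional counterpart and the IVW estimate recomputed.
    """
    from dataclasses import replace

    if conditioning is not None and any(s in conditioning
                                        for s in instr.snp_ids):
        return MrResult(protein_id=instr.protein_id,
                        stratum=Stratum(stratum), is_na=True,
                        instrument_snps=instr.snp_ids)
    by_snp = {c.snp_id: c for c in cond}
    new_snps = []
    for h in instr.snps:
        rec = by_snp.get(h.snp_id)
        if rec is None:
            raise KeyError(f"{instr.protein_id}: no conditional record for "
                           f"instrument SNP {h.snp_id}")
        if not rec.usable:
            return MrResult(protein_id=instr.protein_id,
                            stratum=Stratum(stratum), is_na=True,
                            instrument_snps=instr.snp_ids)
        new_snps.append(replace(h, beta_gy=rec.beta_cond, se_gy=rec.se_cond))
    conditional_set = InstrumentSet(protein_id=instr.protein_id, snps=new_snps)
    return ivw_estimate(conditional_set, stratum=stratum)
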