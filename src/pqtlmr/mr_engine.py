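"""Inverse-variance-weighted Mendelian randomization and multiple-testing control.

The causal effect of a 1-SD increase in genetically predicted protein
concentration on disease log-odds is estimated from k harmonized instruments
as

    beta = sum_i b_xi * b_yi / s_yi**2  /  sum_i b_xi**2 / s_yi**2
    se   = ( sum_i b_xi**2 / s_yi**2 )**-0.5

which is weighted least squares of the outcome betas on the exposure betas
through the origin with weights s_yi**-2, and reduces to the Wald ratio
b_y/b_x for a single SNP.  Exposure-side uncertainty (se_gx) is deliberately
not propagated (the first-order, no-measurement-error IVW estimator); se_gx
is retained in the data model for diagnostics only.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import InstrumentSet, MrResult, Stratum

Z_95 = 1.96  # fixed CI multiplier; two-sided normal throughout


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def ivw_estimate(instr: InstrumentSet,
                 stratum: Stratum | str = Stratum.OVERALL) -> MrResult:
    """Fixed-effects IVW causal estimate for one protein's instrument set.

    An empty instrument set yields an ``is_na`` result (the protein is not
    analyzable in this stratum) rather than an error; a zero exposure beta is
    an error because the ratio estimand is undefined.
    """
    stratum = Stratum(stratum)
    snps = [s for s in instr.snps if s.ok]
    if not snps:
        return MrResult(protein_id=instr.protein_id, stratum=stratum, is_na=True)
    bx = np.array([s.beta_gx for s in snps])
    by = np.array([s.beta_gy for s in snps])
    sy = np.array([s.se_gy for s in snps])
    if np.any(bx == 0):
        raise ValueError(f"{instr.protein_id}: instrument with beta_gx = 0")
    if not np.all(sy > 0):
        raise ValueError(f"{instr.protein_id}: non-positive outcome SE")
    if len(snps) == 1:  # Wald ratio, exactly
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
    else:
        w = sy ** -2.0
        denom = float(np.sum(bx ** 2 * w))
        beta = float(np.sum(bx * by * w)) / denom
        se = denom ** -0.5
    or_, lo, hi = to_odds_ratio(beta, se)
    return MrResult(
        protein_id=instr.protein_id, stratum=stratum,
        beta=beta, se=se, pval=_two_sided_p(beta / se),
        or_=or_, ci_low=lo, ci_high=hi, n_snps=len(snps),
        instrument_snps=[s.snp_id for s in snps],
        cis_trans="; ".join(s.cis_trans for s in snps if s.cis_trans),
    )


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-OR and its 95% Wald interval: (OR, lower, upper)."""
    return (math.exp(beta),
            math.exp(beta - Z_95 * se),
            math.exp(beta + Z_95 * se))


def p_from_or_ci(or_: float, ci_low: float, ci_high: float) -> float:
    """Two-sided p-value implied by an OR with its 95% CI.

    Recovers beta = ln(OR) and se = (ln hi - ln lo) / (2 * 1.96), then returns
    2*(1 - Phi(|beta/se|)).  Useful for checking published OR/CI/p triples for
    internal consistency.
    """
    if not (0.0 < ci_low < ci_high):
        raise ValueError("require 0 < ci_low < ci_high")
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    beta = math.log(or_)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return _two_sided_p(beta / se)


def bh_adjust(pvals: Sequence[float], m_total: Optional[int] = None,
              pad_value: float = 0.5) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    When only the top of the p-value distribution is available (e.g. a
    published table of the strongest hits from ``m_total`` tests), the
    unobserved tests are padded with ``pad_value``; any pad at least as large
    as the largest observed adjusted value leaves the observed adjustments
    unchanged, so the default 0.5 is inert for top-hit tables.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m_total = int(m_total) if m_total is not None else p.size
    if m_total < p.size:
        raise ValueError("m_total must be >= number of observed p-values")
    padded = np.concatenate([p, np.full(m_total - p.size, pad_value)])
    _, adjusted, _, _ = multipletests(padded, method="fdr_bh")
    return adjusted[: p.size]


def bonferroni_threshold(alpha: float, m_total: int) -> float:
    """Family-wise significance threshold alpha / m_total."""
    if not (0 < alpha <= 1) or m_total < 1:
        raise ValueError("require 0 < alpha <= 1 and m_total >= 1")
    return alpha / m_total


def attach_fdr(results: Sequence[MrResult], m_total: Optional[int] = None,
               pad_value: float = 0.5) -> list[MrResult]:
    """Fill ``fdr_p`` across a panel of results (NA results are left as None).

    ``m_total`` defaults to the number of analyzable results, i.e. the size of
    the tested protein panel.
    """
    tested = [r for r in results if not r.is_na]
    if tested:
        adj = bh_adjust([r.pval for r in tested], m_total=m_total,
                        pad_value=pad_value)
        for r, a in zip(tested, adj):
            r.fdr_p = float(a)
    return list(results)
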