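"""Approximate conditional analysis versus individual-level regression."""

import numpy as np
import pytest
import statsmodels.api as sm

from pqtlmr import conditional_estimates, conditional_mr
from pqtlmr.simulate import linear_scan
from pqtlmr.types import (
    ConditionalRecord,
    ConditioningSet,
    HarmonizationStatus,
    HarmonizedInstrument,
    InstrumentSet,
)

from conftest import make_outcome, panel_from_dosages


def _simulate_quantitative(seed, n=5000, n_snps=10, rho=0.5, coefs=None):
    """Individual-level data with AR(1)-correlated SNPs and known coefficients.

    Returns (genotypes, phenotype, marginal OutcomeRecords in continuous mode,
    true joint coefficients).
    """
    rng = np.random.default_rng(seed)
    corr = rho ** np.abs(np.subtract.outer(np.arange(n_snps), np.arange(n_snps)))
    chol = np.linalg.cholesky(corr)
    mafs = rng.uniform(0.2, 0.5, n_snps)
    from scipy.stats import norm
    t = norm.ppf(mafs)
    g = sum(((rng.standard_normal((n, n_snps)) @ chol.T) < t).astype(float)
            for _ in range(2))
    if coefs is None:
        coefs = np.zeros(n_snps)
        coefs[[3, 7]] = [0.3, -0.2]
    y = g @ coefs + rng.normal(0, 1, n)
    beta, se, pval = linear_scan(g, y)
    eaf = g.mean(axis=0) / 2
    records = [make_outcome(snp_id=f"rs{j + 1}", eaf=float(eaf[j]),
                            beta=float(beta[j]), se=float(se[j]),
                            pval=float(pval[j]), n_cases=n, n_controls=0)
               for j in range(n_snps)]
    return g, y, records, coefs


class TestConditionalEstimates:
    def test_empty_conditioning_set_is_identity(self):
        records = [make_outcome(snp_id=f"rs{i}", beta=0.1 * i, se=0.02)
                   for i in range(1, 4)]
        out = conditional_estimates(records, [], panel=None)
        for rec, cond in zip(records, out):
            assert cond.beta_cond == rec.beta_gy
            assert cond.se_cond == rec.se_gy
            assert cond.pval_cond == rec.pval

    def test_orthogonal_conditioning_leaves_marginals(self):
        g, y, records, _ = _simulate_quantitative(seed=0, rho=0.0)
        panel = panel_from_dosages(g, snp_ids=[r.snp_id for r in records])
        out = conditional_estimates(records[:3], records[5:], panel)
        for rec, cond in zip(records[:3], out):
            assert cond.beta_cond == pytest.approx(rec.beta_gy, abs=0.02)

    def test_matches_full_multiple_regression(self):
        g, y, records, _ = _simulate_quantitative(seed=1, rho=0.5)
        panel = panel_from_dosages(g, snp_ids=[r.snp_id for r in records])
        targets, conditioning = records[:3], records[3:]
        out = conditional_estimates(targets, conditioning, panel)
        cond_cols = list(range(3, 10))
        for j, cond in enumerate(out):
            X = sm.add_constant(g[:, [j] + cond_cols])
            fit = sm.OLS(y, X).fit()
            assert cond.beta_cond == pytest.approx(fit.params[1], abs=0.05)
            assert cond.se_cond == pytest.approx(fit.bse[1], rel=0.2)

    def test_collinear_target_flagged_not_estimated(self):
        g, y, records, _ = _simulate_quantitative(seed=2, rho=0.0)
        # target is (nearly) the same variant as a conditioning SNP
        g2 = np.column_stack([g, g[:, 5]])
        ids = [r.snp_id for r in records] + ["rs_dup"]
        panel = panel_from_dosages(g2, snp_ids=ids)
        dup = make_outcome(snp_id="rs_dup", eaf=records[5].eaf,
                           beta=records[5].beta_gy, se=records[5].se_gy,
                           pval=records[5].pval, n_cases=5000, n_controls=0)
        out = conditional_estimates([dup], records[3:], panel)
        assert out[0].dropped_collinear

    def test_pure_ld_leakage_recenters_on_zero(self):
        """A null target correlated with a causal conditioning SNP: the
        marginal effect is LD leakage and conditioning should remove it."""
        ests, margs = [], []
        for seed in range(30):
            coefs = np.zeros(10)
            coefs[1] = 0.4  # causal SNP adjacent to null target SNP 0
            g, y, records, _ = _simulate_quantitative(
                seed=100 + seed, n=2000, rho=0.6, coefs=coefs)
            panel = panel_from_dosages(g, snp_ids=[r.snp_id for r in records])
            out = conditional_estimates([records[0]], [records[1]], panel)
            ests.append(out[0].beta_cond)
            margs.append(records[0].beta_gy)
        assert abs(np.mean(margs)) > 0.05     # leakage present marginally
        assert abs(np.mean(ests)) < 0.02      # removed by conditioning

    def test_freq_mismatch_flagged(self):
        g, y, records, _ = _simulate_quantitative(seed=3, rho=0.0)
        panel = panel_from_dosages(g, snp_ids=[r.snp_id for r in records])
        bad = make_outcome(snp_id="rs1", eaf=0.95,
                           beta=records[0].beta_gy, se=records[0].se_gy,
                           pval=records[0].pval, n_cases=5000, n_controls=0)
        out = conditional_estimates([bad], records[3:], panel)
        assert out[0].dropped_freq_mismatch

    def test_missing_panel_snp_errors(self):
        records = [make_outcome(snp_id="rsX"), make_outcome(snp_id="rsY")]
        panel = panel_from_dosages(
            np.random.default_rng(0).integers(0, 3, (50, 1)).astype(float),
            snp_ids=["rsX"])
        with pytest.raises(KeyError, match="rsY"):
            conditional_estimates([records[0]], [records[1]], panel)

    def test_singular_conditioning_block_errors(self):
        g, y, records, _ = _simulate_quantitative(seed=4, rho=0.0)
        g2 = np.column_stack([g, g[:, 5]])
        ids = [r.snp_id for r in records] + ["rs_dup"]
        panel = panel_from_dosages(g2, snp_ids=ids)
        dup = make_outcome(snp_id="rs_dup", eaf=records[5].eaf,
                           beta=records[5].beta_gy, se=records[5].se_gy,
                           pval=records[5].pval, n_cases=5000, n_controls=0)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            conditional_estimates([records[0]], [records[5], dup], panel)


def _instrument(snp_id, beta_gx, beta_gy, se_gy):
    return HarmonizedInstrument(snp_id=snp_id, beta_gx=beta_gx, se_gx=0.01,
                                beta_gy=beta_gy, se_gy=se_gy,
                                flip_applied=False,
                                status=HarmonizationStatus.OK)


class TestConditionalMr:
    def _iset(self):
        return InstrumentSet(protein_id="P1", snps=[
            _instrument("rs1", 0.5, 0.2, 0.1),
            _instrument("rs2", 1.0, 0.3, 0.1)])

    def test_unchanged_outcome_stats_reproduce_p(self):
        from pqtlmr import ivw_estimate
        iset = self._iset()
        cond = [ConditionalRecord("rs1", 0.2, 0.1, 0.045),
                ConditionalRecord("rs2", 0.3, 0.1, 0.0027)]
        res = conditional_mr(iset, cond)
        base = ivw_estimate(iset)
        assert res.pval == pytest.approx(base.pval, abs=1e-12)

    def test_instrument_in_conditioning_set_is_na(self):
        res = conditional_mr(self._iset(), [],
                             ConditioningSet(snp_ids=("rs2",)))
        assert res.is_na

    def test_halved_betas_halve_estimate(self):
        iset = self._iset()
        full = conditional_mr(iset, [ConditionalRecord("rs1", 0.2, 0.1, 0.05),
                                     ConditionalRecord("rs2", 0.3, 0.1, 0.003)])
        half = conditional_mr(iset, [ConditionalRecord("rs1", 0.1, 0.1, 0.3),
                                     ConditionalRecord("rs2", 0.15, 0.1, 0.1)])
        assert half.beta == pytest.approx(full.beta / 2)

    def test_missing_conditional_record_errors(self):
        with pytest.raises(KeyError, match="rs2"):
            conditional_mr(self._iset(), [ConditionalRecord("rs1", 0.2, 0.1, 0.05)])

    def test_unusable_record_propagates_na(self):
        cond = [ConditionalRecord("rs1", dropped_collinear=True),
                ConditionalRecord("rs2", 0.3, 0.1, 0.003)]
        assert conditional_mr(self._iset(), cond).is_na
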