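import numpy as np
import pandas as pd
import pytest

from pqtlmr import (
    GenotypePanel,
    OutcomeRecord,
    PqtlRecord,
    SimScenario,
    make_fixture_suite,
)


def make_pqtl(snp_id="rs1", chrom="1", pos=100, ea="A", oa="G", eaf=0.3,
              beta=0.3, se=0.02, pval=1e-15, protein="P1", cis_trans="cis"):
    return PqtlRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                      other_allele=oa, eaf=eaf, beta_gx=beta, se_gx=se,
                      pval=pval, protein_id=protein, cis_trans=cis_trans)


def make_outcome(snp_id="rs1", chrom="1", pos=100, ea="A", oa="G", eaf=0.3,
                 beta=0.05, se=0.02, pval=None, n_cases=1000, n_controls=5000,
                 stratum="overall"):
    from scipy import stats
    if pval is None:
        pval = float(min(1.0, 2 * stats.norm.sf(abs(beta / se))))
    return OutcomeRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                         effect_allele=ea, other_allele=oa, eaf=eaf,
                         beta_gy=beta, se_gy=se, pval=pval,
                         n_cases=n_cases, n_controls=n_controls,
                         stratum=stratum)


def panel_from_dosages(dosages, chroms=None, snp_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n_var = dosages.shape[1]
    snp_ids = snp_ids or [f"rs{i + 1}" for i in range(n_var)]
    chroms = chroms or ["1"] * n_var
    variants = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chroms,
        "pos": [100 * (i + 1) for i in range(n_var)],
        "effect_allele": ["A"] * n_var, "other_allele": ["G"] * n_var,
    })
    return GenotypePanel(dosages=dosages, variants=variants)


@pytest.fixture(scope="session")
def fixture_scenario():
    return SimScenario.desk_scale(seed=3)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, fixture_scenario):
    out = tmp_path_factory.mktemp("bundle")
    return make_fixture_suite(out, fixture_scenario)
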