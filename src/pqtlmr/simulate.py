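"""Synthetic pQTL / case-control GWAS data with known ground truth.

The generative model mirrors the design assumptions of a two-sample
proteome-wide MR study:

* a block-structured genotype panel — latent Gaussian haplotypes with AR(1)
  correlation ``within_block_rho`` inside each block, independence across
  blocks (each block is placed on its own chromosome), thresholded to
  Hardy-Weinberg dosages at MAFs drawn from ``maf_range``;
* a protein-measurement cohort (the pQTL study): each protein is a sparse
  linear genetic score plus Gaussian noise, scaled so the protein has unit
  variance, i.e. pQTL effects are per protein SD; per-SNP marginal linear
  regressions of the standardized protein produce the catalog;
* a disjoint disease cohort: case status follows a logistic model whose
  log-odds combine ``logit(baseline_prevalence)``, the per-SD causal effect
  ``theta`` applied to each protein's genetic score, optional random
  per-SNP pleiotropic effects, and optional fixed risk-variant effects;
  cases and controls are sampled to the requested counts and per-SNP
  logistic regressions produce outcome summary statistics (overall and by
  histologic subtype, subtypes being case partitions).

All randomness flows through substreams of one seeded generator, so every
artifact is byte-reproducible from the scenario seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .ld_panel import GenotypePanel, write_panel
from .types import OutcomeRecord, PqtlRecord, Stratum
from .sumstats_io import write_outcome_stats, write_pqtl_catalog

#: non-palindromic allele pairs cycled across variants so that simulated
#: instruments survive harmonization by construction
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T"))

_PVAL_FLOOR = 1e-300  # keep p-values inside (0, 1] for very large |z|


def _default_pqtl_effects() -> dict[str, list[tuple[int, float]]]:
    return {
        "PROT_A": [(0, 0.35), (6, 0.30), (12, 0.28)],
        "PROT_B": [(18, 0.35)],
        "PROT_C": [(24, 0.32)],
    }


def _default_theta() -> dict[str, float]:
    return {"PROT_A": 0.2, "PROT_B": 0.0, "PROT_C": -0.15}


def _default_risk_variants() -> dict[int, float]:
    # SNP 18 is both PROT_B's instrument and a direct risk variant: the
    # analogue of a trans pQTL that is itself a known disease locus.
    return {18: 0.20, 27: 0.12}


@dataclass
class SimScenario:
    """Generative parameters for one synthetic study.

    Defaults describe the desk-scale fixture: 30 SNPs in 6 LD blocks, three
    proteins (one with a 3-SNP instrument and a true effect, one null protein
    whose only instrument is itself a risk variant, one with a single-SNP
    instrument and a protective effect).
    """

    n_snps: int = 30
    n_blocks: int = 6
    within_block_rho: float = 0.6
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_proteins: int = 3
    pqtl_effects: dict[str, list[tuple[int, float]]] = field(
        default_factory=_default_pqtl_effects)
    theta: dict[str, float] = field(default_factory=_default_theta)
    pleiotropy_sd: float = 0.0
    n_exposure: int = 3000
    n_cases: int = 2000
    n_controls: int = 2000
    baseline_prevalence: float = 0.10
    seed: int = 1
    n_panel: int = 500
    risk_variant_effects: dict[int, float] = field(default_factory=dict)
    endometrioid_share: float = 0.75
    theta_by_stratum: Optional[dict[str, dict[str, float]]] = None
    catalog_p_threshold: float = 1.5e-11
    n_population: Optional[int] = None  # outcome source population; auto-sized if None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must be in [0, 1)")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if self.n_proteins != len(self.pqtl_effects):
            raise ValueError("n_proteins must equal len(pqtl_effects)")
        for protein, effects in self.pqtl_effects.items():
            for idx, _ in effects:
                if not (0 <= idx < self.n_snps):
                    raise ValueError(f"{protein}: pQTL index {idx} out of range")
        for idx in self.risk_variant_effects:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"risk variant index {idx} out of range")
        if set(self.theta) != set(self.pqtl_effects):
            raise ValueError("theta must be specified for exactly the proteins "
                             "in pqtl_effects")

    @classmethod
    def desk_scale(cls, seed: int = 1, **kwargs) -> "SimScenario":
        """The default small fixture scenario."""
        kwargs.setdefault("risk_variant_effects", _default_risk_variants())
        return cls(seed=seed, **kwargs)

    @classmethod
    def recovery_benchmark(cls, theta: float = 0.2, seed: int = 1,
                           pleiotropy_sd: float = 0.0) -> "SimScenario":
        """One protein with 3 independent pQTLs for estimator calibration.

        30 SNPs in 6 AR(1) blocks (rho 0.6); exposure cohort of 3000;
        2000 cases / 2000 controls.  MAFs are kept off the low end so all
        three pQTLs clear the catalog significance threshold at this
        exposure-cohort size in every replicate.
        """
        return cls(
            n_snps=30, n_blocks=6, within_block_rho=0.6,
            maf_range=(0.2, 0.45), n_proteins=1,
            pqtl_effects={"PROT_A": [(0, 0.35), (5, 0.32), (10, 0.30)]},
            theta={"PROT_A": theta}, pleiotropy_sd=pleiotropy_sd,
            n_exposure=3000, n_cases=2000, n_controls=2000,
            baseline_prevalence=0.10, seed=seed, n_panel=500,
        )

    @classmethod
    def study_scale(cls, seed: int = 1, **kwargs) -> "SimScenario":
        """Cohort sizes matching the published study design.

        3562 individuals in the protein-measurement cohort and
        12,906 cases / 108,979 controls in the disease GWAS.  Heavy: meant
        for one-off large runs, not the test suite.
        """
        kwargs.setdefault("n_exposure", 3562)
        kwargs.setdefault("n_cases", 12906)
        kwargs.setdefault("n_controls", 108979)
        kwargs.setdefault("baseline_prevalence", 0.03)
        kwargs.setdefault("risk_variant_effects", _default_risk_variants())
        return cls(seed=seed, **kwargs)


@dataclass
class _PopulationModel:
    """Deterministic population parameters shared by panel and both cohorts."""

    mafs: np.ndarray
    thresholds: np.ndarray
    block_slices: list[slice]
    chols: list[np.ndarray]
    variants: pd.DataFrame


def population_model(scenario: SimScenario) -> _PopulationModel:
    rng = np.random.default_rng([scenario.seed, 0])
    mafs = rng.uniform(*scenario.maf_range, size=scenario.n_snps)
    thresholds = stats.norm.ppf(mafs)
    bounds = np.linspace(0, scenario.n_snps, scenario.n_blocks + 1).astype(int)
    block_slices, chols, rows = [], [], []
    for b in range(scenario.n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        m = sl.stop - sl.start
        idx = np.arange(m)
        corr = scenario.within_block_rho ** np.abs(idx[:, None] - idx[None, :])
        block_slices.append(sl)
        chols.append(np.linalg.cholesky(corr))
        for j in range(m):
            i = sl.start + j
            ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
            rows.append({"snp_id": f"rs{101 + i}", "chrom": str(b + 1),
                         "pos": 10_000 + 1_000 * j,
                         "effect_allele": ea, "other_allele": oa})
    variants = pd.DataFrame(rows)
    return _PopulationModel(mafs, thresholds, block_slices, chols, variants)


def _draw_genotypes(model: _PopulationModel, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """HWE dosages with latent-Gaussian LD: two thresholded haplotypes."""
    g = np.empty((n, len(model.mafs)))
    for sl, chol in zip(model.block_slices, model.chols):
        t = model.thresholds[sl]
        m = sl.stop - sl.start
        h1 = (rng.standard_normal((n, m)) @ chol.T) < t
        h2 = (rng.standard_normal((n, m)) @ chol.T) < t
        g[:, sl] = h1.astype(float) + h2.astype(float)
    return g


def simulate_panel(scenario: SimScenario,
                   n_individuals: Optional[int] = None) -> GenotypePanel:
    """Draw an LD reference panel (individuals disjoint from both cohorts)."""
    model = population_model(scenario)
    rng = np.random.default_rng([scenario.seed, 1])
    n = n_individuals if n_individuals is not None else scenario.n_panel
    return GenotypePanel(dosages=_draw_genotypes(model, n, rng),
                         variants=model.variants)


def linear_scan(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of y on each genotype: (beta, se, p)."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    if np.any(sxx == 0):
        raise ValueError("constant genotype column in linear scan")
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    sigma2 = np.maximum(syy - beta * sxy, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), _PVAL_FLOOR)
    return beta, se, p


def logistic_scan(g: np.ndarray, y: np.ndarray, max_iter: int = 30,
                  tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regression (intercept + dosage), Newton-Raphson.

    All columns are fitted simultaneously with closed-form 2x2 Newton steps,
    which keeps many-SNP scans fast at simulation scale.  Returns per-SNP
    (log-OR, SE, two-sided p).
    """
    n, m = g.shape
    ybar = y.mean()
    if not (0.0 < ybar < 1.0):
        raise ValueError("logistic scan requires both cases and controls")
    a = np.full(m, logit(ybar))
    b = np.zeros(m)
    yv = y.astype(float)
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        resid = yv[:, None] - mu
        u0 = resid.sum(axis=0)
        u1 = np.einsum("ij,ij->j", g, resid)
        s0 = w.sum(axis=0)
        s1 = np.einsum("ij,ij->j", g, w)
        s2 = np.einsum("ij,ij->j", g * g, w)
        det = s0 * s2 - s1 * s1
        da = (s2 * u0 - s1 * u1) / det
        db = (s0 * u1 - s1 * u0) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    eta = a[None, :] + g * b[None, :]
    mu = expit(eta)
    w = mu * (1.0 - mu)
    s0 = w.sum(axis=0)
    s1 = np.einsum("ij,ij->j", g, w)
    s2 = np.einsum("ij,ij->j", g * g, w)
    se = np.sqrt(s0 / (s0 * s2 - s1 * s1))
    p = np.maximum(2.0 * stats.norm.sf(np.abs(b / se)), _PVAL_FLOOR)
    return b, se, p


def _effect_vector(scenario: SimScenario, protein: str) -> np.ndarray:
    b = np.zeros(scenario.n_snps)
    for idx, beta in scenario.pqtl_effects[protein]:
        b[idx] += beta
    return b


def _protein_gene_chrom(scenario: SimScenario, model: _PopulationModel,
                        protein: str) -> str:
    first_idx = min(i for i, _ in scenario.pqtl_effects[protein])
    return str(model.variants["chrom"].iloc[first_idx])


def simulate_cohorts(scenario: SimScenario,
                     panel: Optional[GenotypePanel] = None,
                     strata: Optional[Sequence[Stratum]] = None,
                     ) -> tuple[list[PqtlRecord], list[OutcomeRecord], dict]:
    """Simulate both cohorts and reduce them to summary statistics.

    Returns (pQTL catalog records, outcome records across the requested
    strata, truth manifest).  The exposure and outcome cohorts are disjoint
    independent draws from the same population model — the two-sample MR
    assumption holds by construction.  ``panel`` is accepted for interface
    symmetry and checked for consistency; the population model is derived
    from the scenario.
    """
    model = population_model(scenario)
    if panel is not None and list(panel.snp_ids) != list(model.variants["snp_id"]):
        raise ValueError("panel does not match the scenario's population model")
    strata = [Stratum(s) for s in (strata or list(Stratum))]

    rng_exp = np.random.default_rng([scenario.seed, 2])
    rng_out = np.random.default_rng([scenario.seed, 3])

    # ---- exposure (pQTL) cohort -------------------------------------------
    g_exp = _draw_genotypes(model, scenario.n_exposure, rng_exp)
    eaf_exp = g_exp.mean(axis=0) / 2.0
    pqtl_records: list[PqtlRecord] = []
    genetic_var: dict[str, float] = {}
    for protein in sorted(scenario.pqtl_effects):
        bvec = _effect_vector(scenario, protein)
        score = g_exp @ bvec
        var_g = float(score.var())
        genetic_var[protein] = var_g
        noise_var = max(1.0 - var_g, 0.05)
        protein_value = score + rng_exp.normal(0.0, math.sqrt(noise_var),
                                               size=scenario.n_exposure)
        protein_value = (protein_value - protein_value.mean()) / protein_value.std()
        beta, se, pval = linear_scan(g_exp, protein_value)
        gene_chrom = _protein_gene_chrom(scenario, model, protein)
        for j in np.flatnonzero(pval <= scenario.catalog_p_threshold):
            var = model.variants.iloc[j]
            pqtl_records.append(PqtlRecord(
                snp_id=var["snp_id"], chrom=var["chrom"], pos=int(var["pos"]),
                effect_allele=var["effect_allele"],
                other_allele=var["other_allele"],
                eaf=float(eaf_exp[j]), beta_gx=float(beta[j]),
                se_gx=float(se[j]), pval=float(pval[j]),
                protein_id=protein,
                cis_trans="cis" if var["chrom"] == gene_chrom else "trans"))

    # ---- outcome (case-control) cohort ------------------------------------
    prev = scenario.baseline_prevalence
    if scenario.n_population is not None:
        n_pop = scenario.n_population
        if n_pop * prev < scenario.n_cases:
            raise ValueError(
                f"infeasible case count: expected {n_pop * prev:.0f} cases "
                f"from population {n_pop} at prevalence {prev}, "
                f"need {scenario.n_cases}")
    else:
        n_pop = int(math.ceil(1.3 * max(scenario.n_cases / prev,
                                        scenario.n_controls / (1.0 - prev))))
    g_pop = _draw_genotypes(model, n_pop, rng_out)

    pleio = (rng_out.normal(0.0, scenario.pleiotropy_sd, size=scenario.n_snps)
             if scenario.pleiotropy_sd > 0 else np.zeros(scenario.n_snps))
    direct = pleio.copy()
    for idx, eff in scenario.risk_variant_effects.items():
        direct[idx] += eff

    def risk_score(thetas: dict[str, float]) -> np.ndarray:
        score = np.zeros(n_pop)
        for protein, th in thetas.items():
            if th != 0.0:
                gval = g_pop @ _effect_vector(scenario, protein)
                score += th * (gval - gval.mean())
        if np.any(direct != 0.0):
            gd = g_pop - g_pop.mean(axis=0)
            score += gd @ direct
        return score

    subtype_of = np.full(n_pop, -1)  # -1 control, 0 endometrioid, 1 non-endo
    if scenario.theta_by_stratum is None:
        p_case = expit(logit(prev) + risk_score(scenario.theta))
        is_case = rng_out.random(n_pop) < p_case
        labels = rng_out.random(n_pop) >= scenario.endometrioid_share
        subtype_of[is_case] = labels[is_case].astype(int)
    else:
        shares = {Stratum.ENDOMETRIOID: scenario.endometrioid_share,
                  Stratum.NON_ENDOMETRIOID: 1.0 - scenario.endometrioid_share}
        hit = {}
        for st, share in shares.items():
            thetas = scenario.theta_by_stratum.get(st.value, scenario.theta)
            p_case = expit(logit(prev * share) + risk_score(thetas))
            hit[st] = rng_out.random(n_pop) < p_case
        # ties resolved toward the rarer subtype
        subtype_of[hit[Stratum.ENDOMETRIOID]] = 0
        subtype_of[hit[Stratum.NON_ENDOMETRIOID]] = 1
        is_case = subtype_of >= 0

    case_idx = np.flatnonzero(is_case)
    control_idx = np.flatnonzero(~is_case)
    if len(case_idx) < scenario.n_cases:
        raise ValueError(
            f"infeasible case count: population of {n_pop} at prevalence "
            f"{prev} yielded {len(case_idx)} cases < {scenario.n_cases}")
    if len(control_idx) < scenario.n_controls:
        raise ValueError("infeasible control count for requested population")
    cases = rng_out.choice(case_idx, size=scenario.n_cases, replace=False)
    controls = rng_out.choice(control_idx, size=scenario.n_controls,
                              replace=False)

    outcome_records: list[OutcomeRecord] = []
    stratum_counts: dict[str, int] = {}
    for stratum in strata:
        if stratum is Stratum.OVERALL:
            sel_cases = cases
        elif stratum is Stratum.ENDOMETRIOID:
            sel_cases = cases[subtype_of[cases] == 0]
        else:
            sel_cases = cases[subtype_of[cases] == 1]
        stratum_counts[stratum.value] = len(sel_cases)
        if len(sel_cases) == 0:
            continue
        idx = np.concatenate([sel_cases, controls])
        g_s = g_pop[idx]
        y_s = np.concatenate([np.ones(len(sel_cases)),
                              np.zeros(len(controls))])
        beta, se, pval = logistic_scan(g_s, y_s)
        eaf_s = g_s.mean(axis=0) / 2.0
        for j in range(scenario.n_snps):
            var = model.variants.iloc[j]
            outcome_records.append(OutcomeRecord(
                snp_id=var["snp_id"], chrom=var["chrom"], pos=int(var["pos"]),
                effect_allele=var["effect_allele"],
                other_allele=var["other_allele"],
                eaf=float(np.clip(eaf_s[j], 1e-6, 1 - 1e-6)),
                beta_gy=float(beta[j]), se_gy=float(se[j]),
                pval=float(pval[j]), n_cases=len(sel_cases),
                n_controls=len(controls), stratum=stratum))

    truth = {
        "scenario": _scenario_dict(scenario),
        "theta": dict(scenario.theta),
        "genetic_variance": genetic_var,
        "n_population": n_pop,
        "n_cases_drawn": int(len(case_idx)),
        "stratum_case_counts": stratum_counts,
        "risk_variants": {model.variants["snp_id"].iloc[i]: eff
                          for i, eff in scenario.risk_variant_effects.items()},
        "instrument_snps": {
            protein: [model.variants["snp_id"].iloc[i]
                      for i, _ in scenario.pqtl_effects[protein]]
            for protein in scenario.pqtl_effects},
    }
    return pqtl_records, outcome_records, truth


def _scenario_dict(scenario: SimScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["maf_range"] = list(d["maf_range"])
    d["pqtl_effects"] = {k: [[i, b] for i, b in v]
                         for k, v in d["pqtl_effects"].items()}
    d["risk_variant_effects"] = {str(k): v
                                 for k, v in d["risk_variant_effects"].items()}
    return d


def simulate_and_estimate(scenario: SimScenario) -> tuple[dict[str, "MrResult"], dict]:
    """One full synthetic study: simulate, build instruments, IVW-estimate.

    Runs the whole method on one generated dataset (panel + both cohorts,
    overall stratum) and returns per-protein MR results together with the
    truth manifest — the unit of replication for calibration studies
    (bias, CI coverage, type-I error).
    """
    from .instruments import build_instruments
    from .mr_engine import ivw_estimate

    panel = simulate_panel(scenario)
    pqtl_records, outcome_records, truth = simulate_cohorts(
        scenario, panel, strata=[Stratum.OVERALL])
    if not pqtl_records:
        return {}, truth
    sets, _ = build_instruments(
        pqtl_records, outcome_records, panel,
        pqtl_p_threshold=scenario.catalog_p_threshold)
    return {s.protein_id: ivw_estimate(s) for s in sets}, truth


FIXTURE_FILES = {
    "panel_dosages": "panel_dosages.tsv",
    "panel_variants": "panel_variants.tsv",
    "pqtl_catalog": "pqtl_catalog.tsv",
    "outcome_overall": "outcome_overall.tsv",
    "outcome_endometrioid": "outcome_endometrioid.tsv",
    "outcome_non_endometrioid": "outcome_non_endometrioid.tsv",
    "conditioning_snps": "conditioning_snps.txt",
    "truth": "truth.json",
}


def make_fixture_suite(out_dir: str | Path,
                       scenario: Optional[SimScenario] = None) -> dict[str, Path]:
    """Write a complete small scenario bundle in the pipeline's exchange formats.

    Emits the LD panel (dosages + variant map), the pQTL catalog, one outcome
    file per stratum, the conditioning-SNP list (the scenario's risk
    variants) and a JSON truth manifest.  Regeneration with the same scenario
    is byte-identical.
    """
    scenario = scenario if scenario is not None else SimScenario.desk_scale()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in FIXTURE_FILES.items()}

    panel = simulate_panel(scenario)
    write_panel(panel, paths["panel_dosages"], paths["panel_variants"])

    pqtl_records, outcome_records, truth = simulate_cohorts(scenario, panel)
    write_pqtl_catalog(pqtl_records, paths["pqtl_catalog"])
    for stratum in Stratum:
        recs = [r for r in outcome_records if r.stratum is stratum]
        write_outcome_stats(recs, paths[f"outcome_{stratum.value}"])

    risk_ids = sorted(truth["risk_variants"])
    paths["conditioning_snps"].write_text(
        "".join(f"{s}\n" for s in risk_ids))
    paths["truth"].write_text(json.dumps(truth, sort_keys=True, indent=2) + "\n")
    return paths
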