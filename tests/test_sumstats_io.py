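"""Readers, harmonization and fixed-effects meta-analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pqtlmr import (
    HarmonizationStatus,
    fixed_effects_meta,
    harmonize,
    read_outcome_stats,
    read_pqtl_catalog,
    read_results_table,
    write_pqtl_catalog,
    write_results_table,
)
from pqtlmr.mr_engine import ivw_estimate
from pqtlmr.types import InstrumentSet, MrResult

from conftest import make_outcome, make_pqtl

PQTL_HEADER = ("snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\t"
               "beta_gx\tse_gx\tpval\tprotein_id\tcis_trans\n")
OUTCOME_HEADER = ("snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\t"
                  "beta_gy\tse_gy\tpval\tn_cases\tn_controls\n")


def _pqtl_row(snp="rs1", eaf=0.3, pval=1e-15, protein="P1"):
    return f"{snp}\t1\t100\tA\tG\t{eaf}\t0.3\t0.02\t{pval}\t{protein}\tcis\n"


class TestReadPqtlCatalog:
    def test_well_formed_rows_all_parse(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(PQTL_HEADER + _pqtl_row("rs1") + _pqtl_row("rs2")
                        + _pqtl_row("rs3"))
        report = read_pqtl_catalog(path)
        assert report.n_records == 3 and not report.rejects

    def test_out_of_bounds_eaf_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(PQTL_HEADER + _pqtl_row("rs1")
                        + _pqtl_row("rs2", eaf=1.2) + _pqtl_row("rs3"))
        report = read_pqtl_catalog(path)
        assert report.n_records == 2
        assert len(report.rejects) == 1 and report.rejects[0].line == 3

    def test_duplicate_pair_keeps_smaller_p(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(PQTL_HEADER + _pqtl_row("rs1", pval=1e-12)
                        + _pqtl_row("rs1", pval=1e-20))
        report = read_pqtl_catalog(path)
        assert report.n_records == 1
        assert report.records[0].pval == 1e-20
        assert "duplicate" in report.rejects[0].reason

    def test_missing_column_is_fatal(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("snp_id\tchrom\nrs1\t1\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_pqtl_catalog(path)

    def test_round_trip(self, tmp_path):
        records = [make_pqtl(snp_id=f"rs{i}", pval=10.0 ** -(12 + i),
                             beta=0.1 * i) for i in range(1, 4)]
        path = write_pqtl_catalog(records, tmp_path / "out.tsv")
        report = read_pqtl_catalog(path)
        assert report.records == records


class TestReadOutcomeStats:
    def test_well_formed_and_zero_se_rejected(self, tmp_path):
        path = tmp_path / "out.tsv"
        path.write_text(OUTCOME_HEADER
                        + "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.02\t0.012\t100\t500\n"
                        + "rs2\t1\t200\tA\tG\t0.3\t0.05\t0\t0.012\t100\t500\n")
        report = read_outcome_stats(path)
        assert report.n_records == 1
        assert "se_gy" in report.rejects[0].reason

    def test_pval_z_mismatch_warns_but_keeps_row(self, tmp_path):
        path = tmp_path / "out.tsv"
        path.write_text(OUTCOME_HEADER
                        + "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.02\t0.5\t100\t500\n")
        with pytest.warns(UserWarning, match="inconsistent"):
            report = read_outcome_stats(path)
        assert report.n_records == 1 and len(report.warnings) == 1

    def test_duplicate_snp_rejected(self, tmp_path):
        path = tmp_path / "out.tsv"
        row = "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.02\t0.012\t100\t500\n"
        path.write_text(OUTCOME_HEADER + row + row)
        report = read_outcome_stats(path)
        assert report.n_records == 1 and len(report.rejects) == 1


class TestHarmonize:
    def test_identical_alleles_pass_through(self):
        h = harmonize(make_pqtl(ea="A", oa="G", beta=0.3),
                      make_outcome(ea="A", oa="G", beta=0.1))
        assert h.ok and h.beta_gy == 0.1 and not h.flip_applied

    def test_swapped_alleles_flip_sign(self):
        h = harmonize(make_pqtl(ea="A", oa="G", beta=0.3),
                      make_outcome(ea="G", oa="A", beta=0.1, eaf=0.3))
        assert h.ok and h.beta_gy == -0.1 and h.flip_applied

    def test_ambiguous_palindromic_dropped(self):
        h = harmonize(make_pqtl(ea="A", oa="T", eaf=0.48),
                      make_outcome(ea="A", oa="T", eaf=0.48))
        assert h.status is HarmonizationStatus.DROPPED_PALINDROMIC

    def test_clear_maf_palindromic_kept(self):
        h = harmonize(make_pqtl(ea="C", oa="G", eaf=0.10),
                      make_outcome(ea="C", oa="G", eaf=0.12))
        assert h.ok

    def test_allele_mismatch_dropped(self):
        h = harmonize(make_pqtl(ea="A", oa="G"), make_outcome(ea="A", oa="C"))
        assert h.status is HarmonizationStatus.DROPPED_ALLELE_MISMATCH

    def test_snp_id_mismatch_fatal(self):
        with pytest.raises(ValueError, match="mismatch"):
            harmonize(make_pqtl(snp_id="rs1"), make_outcome(snp_id="rs2"))

    def test_swap_preserves_effect_product_sign(self):
        """Swapping the outcome's allele coding must not change the MR signal."""
        x = make_pqtl(ea="A", oa="G", beta=0.3)
        straight = harmonize(x, make_outcome(ea="A", oa="G", beta=0.1))
        swapped = harmonize(x, make_outcome(ea="G", oa="A", beta=-0.1, eaf=0.7))
        assert straight.beta_gx * straight.beta_gy == pytest.approx(
            swapped.beta_gx * swapped.beta_gy)
        est_a = ivw_estimate(InstrumentSet("P1", [straight]))
        est_b = ivw_estimate(InstrumentSet("P1", [swapped]))
        assert est_a.beta == pytest.approx(est_b.beta)


class TestFixedEffectsMeta:
    @pytest.mark.parametrize("betas,ses,expected", [
        ([0.4, 0.4], [0.2, 0.2], (0.4, 0.2 / math.sqrt(2))),
        ([0.7], [0.11], (0.7, 0.11)),
        ([0.2, 0.6], [0.1, 0.3], (0.24, 0.0948683)),  # w = 100, 11.111...
    ])
    def test_pooled_estimates(self, betas, ses, expected):
        beta, se = fixed_effects_meta(betas, ses)
        assert beta == pytest.approx(expected[0], abs=1e-6)
        assert se == pytest.approx(expected[1], abs=1e-6)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fixed_effects_meta([], [])

    @given(b=st.floats(-2, 2), s=st.floats(0.01, 1), k=st.integers(1, 8))
    @settings(deadline=None, max_examples=50)
    def test_identical_studies_shrink_se_by_sqrt_k(self, b, s, k):
        beta, se = fixed_effects_meta([b] * k, [s] * k)
        assert beta == pytest.approx(b, rel=1e-9, abs=1e-12)
        assert se == pytest.approx(s / math.sqrt(k), rel=1e-9)

    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.05, 2)),
                    min_size=2, max_size=6),
           st.floats(-3, 3).filter(lambda c: abs(c) > 1e-3),
           st.randoms(use_true_random=False))
    @settings(deadline=None, max_examples=50)
    def test_permutation_and_scale_consistency(self, studies, c, rnd):
        betas = [b for b, _ in studies]
        ses = [s for _, s in studies]
        pooled, se = fixed_effects_meta(betas, ses)
        shuffled = studies[:]
        rnd.shuffle(shuffled)
        pooled2, se2 = fixed_effects_meta([b for b, _ in shuffled],
                                          [s for _, s in shuffled])
        assert pooled2 == pytest.approx(pooled, rel=1e-9, abs=1e-12)
        assert se2 == pytest.approx(se, rel=1e-9)
        scaled, _ = fixed_effects_meta([c * b for b in betas], ses)
        assert scaled == pytest.approx(c * pooled, rel=1e-9, abs=1e-9)


class TestResultsTable:
    def _results(self):
        out = []
        for i, (beta, se) in enumerate([(0.19, 0.04), (-0.25, 0.06), (0.0, 0.1)]):
            from pqtlmr.mr_engine import to_odds_ratio, _two_sided_p
            or_, lo, hi = to_odds_ratio(beta, se)
            out.append(MrResult(protein_id=f"P{i}", beta=beta, se=se,
                                pval=_two_sided_p(beta / se), or_=or_,
                                ci_low=lo, ci_high=hi, fdr_p=0.04,
                                n_snps=1, instrument_snps=[f"rs{i}"]))
        return out

    def test_three_results_three_rows(self, tmp_path):
        path = write_results_table(self._results(), tmp_path / "r.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 4  # header + 3 data rows

    def test_empty_list_header_only(self, tmp_path):
        path = write_results_table([], tmp_path / "r.tsv")
        assert len(path.read_text().splitlines()) == 1

    def test_round_trip_at_printed_precision(self, tmp_path):
        results = self._results()
        path = write_results_table(results, tmp_path / "r.tsv")
        df = read_results_table(path)
        for res, (_, row) in zip(results, df.iterrows()):
            assert float(row["or"]) == pytest.approx(res.or_, abs=0.005)
            assert float(row["ci_low"]) == pytest.approx(res.ci_low, abs=0.005)
            assert float(row["ci_high"]) == pytest.approx(res.ci_high, abs=0.005)
            assert float(row["pval"]) == pytest.approx(res.pval, rel=0.01)

    def test_na_result_prints_na(self, tmp_path):
        path = write_results_table([MrResult(protein_id="P0", is_na=True)],
                                   tmp_path / "r.tsv")
        assert "NA" in path.read_text().splitlines()[1]
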