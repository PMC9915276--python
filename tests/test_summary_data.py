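"""Data model, I/O, instrument selection, clumping, harmonization, strength."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr import (
    SummaryStatRecord,
    f_statistic,
    harmonize,
    ld_clump,
    read_summary_stats,
    select_instruments,
    variance_explained,
)
from tsmr.summary_data import ConfigurationError


def rec(snp="rs1", chrom="1", pos=100, ea="A", oa="G", beta=0.1, se=0.01,
        pval=1e-9, eaf=None, n=None):
    return SummaryStatRecord(snp, chrom, pos, ea, oa, beta, se, pval, eaf, n)


# ---------------------------------------------------------------------------
# records


class TestRecordValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"se": -1.0},
            {"pval": 0.0},
            {"pval": 1.5},
            {"pos": 0},
            {"ea": "A", "oa": "A"},
            {"eaf": 1.2},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rec(**kwargs)

    def test_maf_is_minor_allele_frequency(self):
        assert rec(eaf=0.7).maf == pytest.approx(0.3)
        assert rec(eaf=0.3).maf == pytest.approx(0.3)
        assert rec().maf is None

    def test_palindromic_detection(self):
        assert rec(ea="A", oa="T").is_palindromic()
        assert rec(ea="G", oa="C").is_palindromic()
        assert not rec(ea="A", oa="G").is_palindromic()


# ---------------------------------------------------------------------------
# I/O


class TestReadSummaryStats:
    HEADER = "snp\tchr\tpos\tea\toa\tbeta\tse\tpval\n"

    def test_reads_packaged_table_shape(self, severity):
        # the packaged severity table re-serialized through the generic reader
        buf = io.StringIO()
        df = severity.records.rename(
            columns={
                "beta_exposure": "beta", "se_exposure": "se", "pval_exposure": "pval",
                "chrom": "chr",
            }
        )
        df["ea"], df["oa"] = "A", "G"
        df[["snp", "chr", "pos", "ea", "oa", "beta", "se", "pval"]].to_csv(
            buf, sep="\t", index=False
        )
        buf.seek(0)
        records = read_summary_stats(buf, delimiter="\t")
        assert len(records) == 20
        assert records[0].snp_id == "rs10850097"

    def test_empty_data_section_is_empty_list(self):
        records = read_summary_stats(io.StringIO(self.HEADER), delimiter="\t")
        assert records == []

    def test_zero_se_row_dropped_and_counted(self):
        body = "rs1\t1\t100\tA\tG\t0.1\t0\t1e-9\nrs2\t1\t200\tA\tG\t0.1\t0.01\t1e-9\n"
        records, report = read_summary_stats(
            io.StringIO(self.HEADER + body), delimiter="\t", return_report=True
        )
        assert [r.snp_id for r in records] == ["rs2"]
        assert report["n_dropped"] == 1

    def test_unparsable_beta_dropped(self):
        body = "rs1\t1\t100\tA\tG\tnot_a_number\t0.01\t1e-9\n"
        records, report = read_summary_stats(
            io.StringIO(self.HEADER + body), delimiter="\t", return_report=True
        )
        assert records == [] and report["n_dropped"] == 1

    def test_missing_required_column_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            read_summary_stats(io.StringIO("snp\tbeta\nrs1\t0.1\n"), delimiter="\t")

    def test_column_map_binds_nonstandard_names(self):
        text = "rsid,chrom,bp,A1,A2,b,stderr,p\nrs9,2,500,A,G,0.2,0.02,1e-10\n"
        records = read_summary_stats(
            io.StringIO(text),
            column_map={"snp": "rsid", "chr": "chrom", "pos": "bp", "ea": "A1",
                        "oa": "A2", "beta": "b", "se": "stderr", "pval": "p"},
            delimiter=",",
        )
        assert records[0].snp_id == "rs9" and records[0].beta == 0.2


# ---------------------------------------------------------------------------
# selection


class TestSelectInstruments:
    def test_strict_inequality_at_threshold(self):
        records = [rec(snp="a", pval=1e-9), rec(snp="b", pval=1e-7), rec(snp="c", pval=5e-8)]
        kept = select_instruments(records, 5e-8)
        assert [r.snp_id for r in kept] == ["a"]

    def test_all_packaged_severity_instruments_pass_genome_wide(self, severity):
        records = [
            rec(snp=s, pval=p)
            for s, p in zip(severity.records["snp"], severity.records["pval_exposure"])
        ]
        assert len(select_instruments(records, 5e-8)) == 20

    def test_empty_input(self):
        assert select_instruments([], 5e-8) == []

    @given(st.lists(st.floats(1e-300, 1.0), min_size=0, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, pvals):
        records = [rec(snp=f"rs{i}", pval=p) for i, p in enumerate(pvals)]
        once = select_instruments(records, 5e-8)
        assert select_instruments(once, 5e-8) == once


# ---------------------------------------------------------------------------
# clumping


def greedy_clump_oracle(records, ld, r2_thr, dist_kb):
    """Step-by-step greedy enumeration, independent of the implementation."""
    alive = {r.snp_id for r in records}
    idx = {r.snp_id: i for i, r in enumerate(records)}
    kept = []
    while alive:
        lead = min(alive, key=lambda s: (records[idx[s]].pval, s))
        kept.append(lead)
        alive.discard(lead)
        li = idx[lead]
        for other in list(alive):
            oi = idx[other]
            same_near = (
                records[oi].chrom == records[li].chrom
                and abs(records[oi].pos - records[li].pos) / 1000 < dist_kb
            )
            if ld[li, oi] > r2_thr or same_near:
                alive.discard(other)
    return sorted(kept)


class TestLdClump:
    def test_distance_rule_removes_nearby_weaker_snp(self):
        records = [
            rec(snp="strong", chrom="1", pos=1_000_000, pval=1e-20),
            rec(snp="weak", chrom="1", pos=6_000_000, pval=1e-9),  # 5,000 kb away
        ]
        kept = ld_clump(records, np.eye(2), 0.001, 10_000)
        assert [r.snp_id for r in kept] == ["strong"]

    def test_unlinked_snps_on_different_chromosomes_all_survive(self):
        records = [rec(snp=f"rs{i}", chrom=str(i + 1), pos=100, pval=1e-9) for i in range(3)]
        kept = ld_clump(records, np.eye(3), 0.001, 10_000)
        assert len(kept) == 3

    def test_chained_ld_keeps_ends(self):
        # A-B r2 0.5, B-C r2 0.5, A-C r2 0; pvals A < B < C
        records = [
            rec(snp="A", chrom="1", pos=1, pval=1e-12),
            rec(snp="B", chrom="2", pos=1, pval=1e-10),
            rec(snp="C", chrom="3", pos=1, pval=1e-8),
        ]
        ld = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]])
        kept = ld_clump(records, ld, 0.001, 10_000)
        assert sorted(r.snp_id for r in kept) == ["A", "C"]
        assert greedy_clump_oracle(records, ld, 0.001, 10_000) == ["A", "C"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_greedy_oracle_and_is_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        records = [
            rec(snp=f"rs{i}", chrom=str(rng.integers(1, 4)),
                pos=int(rng.integers(1, 50_000_000)), pval=float(rng.uniform(1e-30, 1e-8)))
            for i in range(n)
        ]
        ld = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = np.where(rng.random(len(iu[0])) < 0.3, rng.uniform(0.1, 0.9, len(iu[0])), 0.0)
        ld[iu] = vals
        ld = ld + ld.T + np.eye(n)
        kept = ld_clump(records, ld, 0.001, 10_000)
        assert sorted(r.snp_id for r in kept) == greedy_clump_oracle(records, ld, 0.001, 10_000)
        # permuting the input leaves the surviving set and its order unchanged
        perm = rng.permutation(n)
        kept_perm = ld_clump([records[i] for i in perm], ld[np.ix_(perm, perm)], 0.001, 10_000)
        assert [r.snp_id for r in kept_perm] == [r.snp_id for r in kept]

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            ld_clump([rec()], np.eye(2), 0.001, 10_000)


# ---------------------------------------------------------------------------
# harmonization


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        ex = [rec(ea="A", oa="G", beta=0.1)]
        ou = [rec(ea="G", oa="A", beta=0.2)]
        hs = harmonize(ex, ou)
        assert hs.records["beta_outcome"].iloc[0] == pytest.approx(-0.2)

    def test_identical_coding_unchanged(self):
        hs = harmonize([rec(beta=0.1)], [rec(beta=0.2)])
        assert hs.records["beta_outcome"].iloc[0] == pytest.approx(0.2)

    def test_strand_flip_without_swap_keeps_sign(self):
        ex = [rec(ea="A", oa="G", beta=0.1)]
        ou = [rec(ea="T", oa="C", beta=0.2)]
        hs = harmonize(ex, ou)
        assert hs.records["beta_outcome"].iloc[0] == pytest.approx(0.2)

    def test_palindromic_policies(self):
        ex = [rec(ea="A", oa="T", eaf=0.30), rec(snp="rs2")]
        ou = [rec(ea="A", oa="T", eaf=0.31, beta=0.2), rec(snp="rs2")]
        inferred = harmonize(ex, ou, palindromic_policy="infer_by_eaf")
        assert "rs1" in inferred.snp_ids
        assert inferred.records.set_index("snp").loc["rs1", "beta_outcome"] == pytest.approx(0.2)
        dropped = harmonize(ex, ou, palindromic_policy="drop")
        assert "rs1" not in dropped.snp_ids

    def test_palindromic_ambiguous_eaf_dropped(self):
        ex = [rec(ea="A", oa="T", eaf=0.50), rec(snp="rs2")]
        ou = [rec(ea="A", oa="T", eaf=0.50), rec(snp="rs2")]
        hs = harmonize(ex, ou, palindromic_policy="infer_by_eaf")
        assert "rs1" not in hs.snp_ids

    def test_palindromic_opposite_eaf_sides_flips(self):
        ex = [rec(ea="A", oa="T", eaf=0.30), rec(snp="rs2")]
        ou = [rec(ea="A", oa="T", eaf=0.70, beta=0.2), rec(snp="rs2")]
        hs = harmonize(ex, ou, palindromic_policy="infer_by_eaf")
        assert hs.records.set_index("snp").loc["rs1", "beta_outcome"] == pytest.approx(-0.2)

    def test_allele_mismatch_dropped_with_reason(self):
        ex = [rec(ea="A", oa="G"), rec(snp="rs2")]
        ou = [rec(ea="A", oa="C"), rec(snp="rs2")]
        hs = harmonize(ex, ou)
        assert "rs1" not in hs.snp_ids
        assert "allele mismatch" in hs.provenance

    def test_harmonizing_twice_equals_once(self):
        rng = np.random.default_rng(0)
        ex, ou = [], []
        for i in range(10):
            beta_o = float(rng.normal(0, 0.1))
            swapped = i % 2 == 0
            ex.append(rec(snp=f"rs{i}", ea="A", oa="G", beta=float(rng.normal(0.1, 0.02))))
            ou.append(
                rec(snp=f"rs{i}", ea="G" if swapped else "A", oa="A" if swapped else "G",
                    beta=beta_o)
            )
        once = harmonize(ex, ou)
        # feed the harmonized records back as both sides' orientation source
        ex2 = [
            rec(snp=row.snp, ea=row.effect_allele, oa=row.other_allele,
                beta=row.beta_exposure, se=row.se_exposure, pval=row.pval_exposure)
            for row in once.records.itertuples()
        ]
        ou2 = [
            rec(snp=row.snp, ea=row.effect_allele, oa=row.other_allele,
                beta=row.beta_outcome, se=row.se_outcome, pval=row.pval_outcome)
            for row in once.records.itertuples()
        ]
        twice = harmonize(ex2, ou2)
        np.testing.assert_allclose(
            twice.records["beta_outcome"], once.records["beta_outcome"]
        )


# ---------------------------------------------------------------------------
# instrument strength


class TestStrength:
    def test_zero_effect_explains_nothing(self):
        assert variance_explained(0.0, 0.01, 10_000, 0.3) == 0.0

    def test_known_value(self):
        # z = 10, R2 = 100 / (100 + 9998)
        assert variance_explained(0.1, 0.01, 10_000, 0.3) == pytest.approx(
            100 / 10098, rel=1e-12
        )

    def test_monotone_in_precision(self):
        r2s = [variance_explained(0.1, se, 10_000, 0.3) for se in (0.02, 0.01, 0.005)]
        assert r2s == sorted(r2s)

    def test_maf_domain(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.01, 10_000, 0.6)

    def test_f_zero_and_known_value(self):
        assert f_statistic(0.0, 100, 1) == 0.0
        assert f_statistic(0.01, 1001, 1) == pytest.approx((0.01 / 0.99) * 999, rel=1e-12)

    def test_f_decreases_with_more_instruments(self):
        assert f_statistic(0.01, 1001, 2) < f_statistic(0.01, 1001, 1)

    def test_f_matches_arithmetic_oracle_on_random_tuples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            r2 = float(rng.uniform(0, 0.5))
            m = int(rng.integers(1, 20))
            n = int(rng.integers(m + 2, 10_000))
            expected = r2 / (1 - r2) * (n - m - 1) / m  # independent arithmetic path
            assert f_statistic(r2, n, m) == pytest.approx(expected, rel=1e-12)

    def test_f_invalid_sample_size(self):
        with pytest.raises(ValueError):
            f_statistic(0.01, 3, 2)


# ---------------------------------------------------------------------------
# serialization round-trips


class TestSerialization:
    def test_harmonized_set_tsv_round_trip(self, severity, tmp_path):
        path = tmp_path / "set.tsv"
        severity.to_tsv(path)
        from tsmr import HarmonizedSet

        back = HarmonizedSet.from_tsv(path)
        assert back.snp_ids == severity.snp_ids
        np.testing.assert_allclose(back.by, severity.by)
        np.testing.assert_allclose(back.sy, severity.sy)

    def test_ld_matrix_reader_validates(self, tmp_path):
        from tsmr import read_ld_matrix

        good = tmp_path / "ld.tsv"
        good.write_text("rs1\trs2\n1.0\t0.3\n0.3\t1.0\n")
        ids, mat = read_ld_matrix(good)
        assert ids == ["rs1", "rs2"]
        assert mat[0, 1] == 0.3
        bad = tmp_path / "bad.tsv"
        bad.write_text("rs1\trs2\n1.0\t1.3\n1.3\t1.0\n")
        with pytest.raises(ValueError):
            read_ld_matrix(bad)

    def test_summary_stats_round_trip(self, tmp_path):
        from tsmr import read_summary_stats, write_summary_stats

        records = [rec(snp=f"rs{i}", pos=100 + i, beta=0.1 * i + 0.05, eaf=0.2, n=1000)
                   for i in range(4)]
        path = tmp_path / "stats.tsv"
        write_summary_stats(records, path)
        back = read_summary_stats(path, delimiter="\t")
        assert [r.snp_id for r in back] == [r.snp_id for r in records]
        assert back[2].beta == pytest.approx(records[2].beta)
        assert back[0].eaf == 0.2 and back[0].n == 1000
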