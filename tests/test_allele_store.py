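import numpy as np
import pytest
from hypothesis import given, strategies as st

import beaconkit as bk
from beaconkit import allele_store as store
from beaconkit.errors import (
    AssemblyMismatchError,
    DegenerateAlleleError,
    IngestError,
    UnsupportedAlleleError,
)
from conftest import random_allele_keys


class TestNormalizeAllele:
    @pytest.mark.parametrize(
        "chrom,pos,ref,alt,want",
        [
            # worked example: C observed at 1-based 32,936,732 on chromosome 13
            ("13", 32936732, "G", "C", ("13", 32936731, "G", "C")),
            ("chr13", 32936732, "g", "c", ("13", 32936731, "G", "C")),
            # shared suffix then prefix trimming, start advances past the prefix
            ("1", 100, "CAG", "CTG", ("1", 100, "A", "T")),
            ("1", 100, "A", "AT", ("1", 99, "A", "AT")),  # insertion untouched
            ("1", 100, "ATT", "AT", ("1", 99, "AT", "A")),  # suffix trim only
        ],
    )
    def test_canonical_form(self, chrom, pos, ref, alt, want):
        key = bk.normalize_allele(chrom, pos, ref, alt, "GRCh37")
        assert (key.chromosome, key.start, key.ref_bases, key.alt_bases) == want
        assert key.assembly_id == "GRCh37"

    def test_identical_alleles_are_degenerate(self):
        with pytest.raises(DegenerateAlleleError):
            bk.normalize_allele("1", 100, "AT", "AT", "GRCh37")

    @pytest.mark.parametrize("alt", ["<DEL>", "C[2:321682[", "N", "A.C", ""])
    def test_non_acgt_alleles_rejected(self, alt):
        with pytest.raises(UnsupportedAlleleError):
            bk.normalize_allele("1", 100, "A", alt, "GRCh37")

    def test_position_and_chromosome_contracts(self):
        with pytest.raises(ValueError):
            bk.normalize_allele("1", 0, "A", "C", "GRCh37")
        with pytest.raises(ValueError):
            bk.normalize_allele("", 10, "A", "C", "GRCh37")

    @given(
        pos=st.integers(min_value=1, max_value=10**6),
        ref=st.text(alphabet="ACGT", min_size=1, max_size=6),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    def test_normalization_is_idempotent(self, pos, ref, alt):
        try:
            key = bk.normalize_allele("7", pos, ref, alt, "GRCh38")
        except DegenerateAlleleError:
            return
        again = bk.normalize_allele(
            key.chromosome, key.start + 1, key.ref_bases, key.alt_bases, "GRCh38"
        )
        assert again == key
        assert key.ref_bases != key.alt_bases
        assert key.start >= 0


class TestIngest:
    def test_example_fixture_single_record(self, example_vcf):
        index = bk.ingest_vcf(example_vcf, "ds", "GRCh37")
        assert index.record_count == 1
        key = bk.normalize_allele("13", 32936732, "G", "C", "GRCh37")
        record = bk.lookup(index, key)
        assert record is not None
        # bare line: no counts, so no frequency either
        assert record.allele_count is None
        assert bk.allele_frequency(record) is None

    def test_multiallelic_split_uses_info_counts(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AC,Number=A,Type=Integer,Description="x">\n'
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="x">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\t.\tA\tC,T\t.\t.\tAC=3,5;AN=200\n"
        )
        index = bk.ingest_vcf(path, "ds", "GRCh37")
        assert index.record_count == 2
        rec_c = bk.lookup(index, bk.normalize_allele("1", 100, "A", "C", "GRCh37"))
        rec_t = bk.lookup(index, bk.normalize_allele("1", 100, "A", "T", "GRCh37"))
        assert (rec_c.allele_count, rec_c.call_count) == (3, 200)
        assert (rec_t.allele_count, rec_t.call_count) == (5, 200)
        assert bk.allele_frequency(rec_t) == pytest.approx(0.025)

    def test_counts_fall_back_to_genotypes(self, tmp_path):
        path = tmp_path / "gt.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=2>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "2\t50\t.\tG\tA\t.\t.\t.\tGT\t0/1\t1|1\t./.\n"
        )
        index = bk.ingest_vcf(path, "ds", "GRCh37")
        rec = bk.lookup(index, bk.normalize_allele("2", 50, "G", "A", "GRCh37"))
        # 3 alt copies among 4 called alleles ('.' is missing), 2 carriers
        assert (rec.allele_count, rec.call_count, rec.sample_count) == (3, 4, 2)
        assert index.sample_total == 3

    def test_symbolic_alt_skipped_not_fatal(self, tmp_path):
        path = tmp_path / "sym.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##ALT=<ID=DEL,Description=\"Deletion\">\n"
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t10\t.\tA\t<DEL>\t.\t.\t.\n"
            "1\t20\t.\tC\tG\t.\t.\t.\n"
        )
        index = bk.ingest_vcf(path, "ds", "GRCh37")
        assert index.record_count == 1

    def test_duplicate_keys_merge_conserves_allele_count(self, tmp_path):
        path = tmp_path / "dup.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AC,Number=A,Type=Integer,Description="x">\n'
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="x">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\t.\tA\tC\t.\t.\tAC=2;AN=10\n"
            "1\t99\t.\tGAC\tGCC\t.\t.\tAC=4;AN=12\n"  # normalizes to 1:100 A>C
        )
        index = bk.ingest_vcf(path, "ds", "GRCh37")
        assert index.record_count == 1
        rec = bk.lookup(index, bk.normalize_allele("1", 100, "A", "C", "GRCh37"))
        assert rec.allele_count == 2 + 4
        assert rec.call_count == 10 + 12

    def test_empty_vcf_yields_empty_index(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        assert bk.ingest_vcf(path, "ds", "GRCh37").record_count == 0

    def test_garbled_file_raises_ingest_error_naming_file(self, tmp_path):
        path = tmp_path / "garbled.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(IngestError, match="garbled.vcf"):
            bk.ingest_vcf(path, "ds", "GRCh37")


class TestLookup:
    def test_absent_alt_is_absent_not_error(self, example_vcf):
        index = bk.ingest_vcf(example_vcf, "ds", "GRCh37")
        key = bk.normalize_allele("13", 32936732, "G", "A", "GRCh37")
        assert bk.lookup(index, key) is None

    def test_assembly_mismatch_is_typed(self, example_vcf):
        index = bk.ingest_vcf(example_vcf, "ds", "GRCh37")
        key = bk.normalize_allele("13", 32936732, "G", "C", "GRCh38")
        with pytest.raises(AssemblyMismatchError):
            bk.lookup(index, key)

    def test_verdicts_match_linear_scan_oracle(self, small_index):
        rng = np.random.default_rng(77)
        all_records = list(small_index.records.values())
        for key in random_allele_keys(rng, 300):
            oracle = any(r.key == key for r in all_records)  # brute-force scan
            assert (bk.lookup(small_index, key) is not None) == oracle


class TestRoundTrip:
    def test_every_emitted_allele_is_found(self, small_population, small_vcf):
        from beaconkit.attack_sim import population_allele_keys

        index = bk.ingest_vcf(small_vcf, "small", "SYNTH")
        truth = population_allele_keys(small_population, range(30), "SYNTH")
        assert index.record_count == len(truth)
        members = np.arange(30)
        an = 2 * len(members)
        for chrom, start, ref, alt in truth:
            rec = bk.lookup(
                index,
                bk.AlleleKey("SYNTH", chrom, start, ref, alt),
            )
            assert rec is not None
            # AC conservation: INFO AC equals the sum of member dosages
            assert rec.allele_count == int(
                small_population.genotypes[members, start].sum()
            )
            assert rec.call_count == an

    def test_persistence_round_trip(self, small_index, tmp_path):
        path = tmp_path / "index.json"
        bk.save_index(small_index, path)
        loaded = bk.load_index(path)
        assert loaded.record_count == small_index.record_count
        assert loaded.records == small_index.records
        assert loaded.sample_total == small_index.sample_total


@pytest.mark.parametrize(
    "ac,an,want",
    [(1, 2, 0.5), (3, 200, 0.015), (5, None, None), (None, 100, None)],
)
def test_allele_frequency_contract(ac, an, want):
    key = bk.AlleleKey("GRCh37", "1", 0, "A", "C")
    rec = bk.ObservationRecord(key=key, allele_count=ac, call_count=an)
    assert bk.allele_frequency(rec) == (pytest.approx(want) if want else want)
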