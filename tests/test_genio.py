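"""Data model, VCF round trips, windowing and LD pruning."""

import numpy as np
import pytest

from introkit.genio import (
    HaplotypeMatrix,
    SampleTable,
    ld_prune,
    pop_allele_freq,
    read_gene_annotations,
    read_vcf,
    windows_by_bp,
    windows_by_snp_count,
    write_vcf,
)
from conftest import make_matrix


class TestHaplotypeMatrix:
    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError, match="increasing"):
            make_matrix(np.zeros((2, 3)), pos=[10, 5, 20])

    def test_rejects_odd_haplotype_rows(self):
        with pytest.raises(ValueError, match="2 per sample"):
            HaplotypeMatrix(
                alleles=np.zeros((3, 1), dtype=np.int8), sample_ids=["a"],
                chrom=np.array(["c"]), pos=np.array([1]),
                ref=np.array(["A"]), alt=np.array(["T"]))

    def test_sample_row_lookup(self, random_matrix):
        rows = random_matrix.rows_for_samples(["s3", "s0"])
        assert rows.tolist() == [6, 7, 0, 1]
        with pytest.raises(KeyError):
            random_matrix.rows_for_samples(["nope"])


class TestVcfRoundTrip:
    def test_write_read_identity(self, random_matrix, tmp_path):
        p = tmp_path / "m.vcf"
        write_vcf(random_matrix, p, seed=7)
        back = read_vcf(p)
        assert np.array_equal(back.alleles, random_matrix.alleles)
        assert np.array_equal(back.pos, random_matrix.pos)
        assert back.sample_ids == random_matrix.sample_ids

    def test_missing_alleles_round_trip(self, tmp_path):
        m = make_matrix([[0, 1], [-1, -1], [1, 0], [0, -1]])
        p = tmp_path / "m.vcf"
        write_vcf(m, p)
        back = read_vcf(p)
        assert np.array_equal(back.alleles, m.alleles)

    def test_empty_matrix_header_only(self, tmp_path):
        m = make_matrix(np.empty((4, 0), dtype=np.int8))
        p = tmp_path / "empty.vcf"
        write_vcf(m, p)
        text = p.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        back = read_vcf(p)
        assert back.n_sites == 0 and back.sample_ids == m.sample_ids

    def test_multiallelic_skipped_with_count(self, tmp_path):
        p = tmp_path / "multi.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "chr1\t200\t.\tA\tC,T\t.\tPASS\t.\tGT\t0|1\t0|2\n"
            "chr1\t300\t.\tG\tC\t.\tPASS\t.\tGT\t0|0\t0|1\n")
        with pytest.warns(UserWarning, match="skipped 1"):
            m = read_vcf(p)
        assert m.n_sites == 2
        assert m.pos.tolist() == [100, 300]
        assert m.alleles.shape == (4, 2)

    def test_unphased_het_rejected_unless_allowed(self, tmp_path):
        p = tmp_path / "unphased.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="unphased"):
            read_vcf(p)
        m = read_vcf(p, allow_unphased=True, seed=1)
        assert sorted(m.alleles[:, 0].tolist()) == [0, 1]

    def test_region_filter(self, random_matrix, tmp_path):
        p = tmp_path / "m.vcf"
        write_vcf(random_matrix, p)
        sub = read_vcf(p, region="chr1:1-5001")
        assert sub.n_sites == 6  # positions 1,1001,...,5001
        assert read_vcf(p, region="chrX").n_sites == 0


class TestWindowsBySnpCount:
    @pytest.mark.parametrize("S,expected", [
        (300, [(0, 150), (75, 225), (150, 300)]),
        (150, [(0, 150)]),
        (310, [(0, 150), (75, 225), (150, 300), (225, 310)]),
    ])
    def test_window_layout(self, S, expected):
        m = make_matrix(np.zeros((2, S), dtype=np.int8))
        wins = windows_by_snp_count(m, size=150, step=75)
        assert [(w.start_idx, w.stop_idx) for w in wins] == expected

    def test_short_chromosome_warns_and_skips(self):
        m = make_matrix(np.zeros((2, 100), dtype=np.int8))
        with pytest.warns(UserWarning, match="no windows"):
            assert windows_by_snp_count(m, size=150, step=75) == []

    def test_each_snp_in_at_most_two_windows(self):
        m = make_matrix(np.zeros((2, 500), dtype=np.int8))
        wins = windows_by_snp_count(m, size=150, step=75)
        cover = np.zeros(500, dtype=int)
        for w in wins:
            cover[w.start_idx:w.stop_idx] += 1
        assert cover.max() <= 2 and cover.min() >= 1


class TestWindowsByBp:
    def test_tiling_rule(self):
        pos = np.arange(1000, 250_001, 1000)
        m = make_matrix(np.zeros((2, len(pos)), dtype=np.int8), pos=pos)
        wins = windows_by_bp(m, size=100_000, step=50_000)
        assert [w.start_bp for w in wins] == [1, 50_001, 100_001, 150_001]

    def test_boundary_snp_in_two_windows(self):
        pos = np.array([100_000, 150_000])
        m = make_matrix(np.zeros((2, 2), dtype=np.int8), pos=pos)
        wins = windows_by_bp(m, size=100_000, step=50_000)
        holding = [w for w in wins
                   if w.start_idx <= 0 < w.stop_idx]
        assert [(w.start_bp, w.end_bp) for w in holding] == [
            (1, 100_000), (50_001, 150_000)]

    def test_empty_windows_retained(self):
        pos = np.array([1, 300_000])
        m = make_matrix(np.zeros((2, 2), dtype=np.int8), pos=pos)
        wins = windows_by_bp(m, size=100_000, step=50_000)
        assert any(w.n_snps == 0 for w in wins)


class TestPopAlleleFreq:
    def test_basic_and_missing(self):
        m = make_matrix([[0, 0, -1], [1, -1, -1], [1, 1, -1], [1, 1, -1]])
        freq, n = pop_allele_freq(m, ["s0", "s1"])
        assert freq[0] == pytest.approx(0.75)
        assert freq[1] == pytest.approx(2 / 3)
        assert np.isnan(freq[2]) and n[2] == 0

    def test_unknown_sample_errors(self, random_matrix):
        with pytest.raises(KeyError):
            pop_allele_freq(random_matrix, ["ghost"])


class TestLdPrune:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        col = (rng.random(20) < 0.5).astype(np.int8)
        other = (rng.random(20) < 0.5).astype(np.int8)
        m = make_matrix(np.column_stack([col, col, other]))
        kept = ld_prune(m)
        assert 0 in kept and 1 not in kept

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(1)
        m = make_matrix((rng.random((1000, 2)) < 0.5).astype(np.int8))
        assert ld_prune(m).tolist() == [0, 1]

    def test_r2_max_one_keeps_everything(self, random_matrix):
        kept = ld_prune(random_matrix, r2_max=1.0)
        assert kept.tolist() == list(range(200))

    def test_idempotent_and_subset(self, random_matrix):
        kept = ld_prune(random_matrix)
        assert set(kept) <= set(range(200))
        pruned = random_matrix.take_sites(kept)
        again = ld_prune(pruned)
        assert len(again) == len(kept)


class TestGeneAnnotations:
    def test_bed_coordinate_shift(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr6\t17899999\t18000000\n")
        gt = read_gene_annotations(p, format="bed")
        assert gt.df.loc[0, "start"] == 17_900_000
        assert gt.df.loc[0, "end"] == 18_000_000

    def test_gff3_gene_features_only(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1;Name=G1\n"
            "chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=g1\n")
        gt = read_gene_annotations(p, format="gff3")
        assert len(gt) == 1 and gt.df.loc[0, "gene_id"] == "g1"

    def test_mrna_only_gff3_warns_empty(self, tmp_path):
        p = tmp_path / "mrna.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1\n")
        with pytest.warns(UserWarning, match="no 'gene'"):
            gt = read_gene_annotations(p, format="gff3")
        assert len(gt) == 0

    def test_unsorted_bed_sorted_output(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr2\t0\t10\tb\nchr1\t500\t600\ta2\nchr1\t0\t10\ta1\n")
        gt = read_gene_annotations(p, format="bed")
        assert gt.df["gene_id"].tolist() == ["a1", "a2", "b"]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown annotation format"):
            read_gene_annotations(tmp_path / "x", format="gtf")


class TestSampleTable:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleTable.from_records([("a", "p", "target"), ("a", "q", "target")])

    def test_groups_and_targets(self):
        t = SampleTable.from_records([
            ("a", "pop1", "reference"), ("b", "pop2", "reference"),
            ("c", "pop1", "target")])
        assert t.reference_groups() == {"pop1": ["a"], "pop2": ["b"]}
        assert t.targets() == ["c"]
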