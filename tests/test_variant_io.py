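"""VCF I/O, depth filtering, MNP decomposition, frequencies, region tags."""

import numpy as np
import pytest

from milkvar.variant_io import (
    GenotypeMatrix,
    VariantRecord,
    allele_frequency,
    apply_variants,
    classify_region,
    decompose_mnp,
    filter_by_depth,
    normalize,
    read_vcf,
    round_half_away,
    write_vcf,
)


def _matrix(genotypes, depths=None, groups=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_v, n_a, _ = genotypes.shape
    if depths is None:
        depths = np.full((n_v, n_a), 30, dtype=np.int32)
    groups = groups or ["ALL"] * n_a
    animals = [(f"A{i}", g) for i, g in enumerate(groups)]
    variants = [
        VariantRecord("1", 100 + i, "A", "G", f"v{i}") for i in range(n_v)
    ]
    return GenotypeMatrix(variants, animals, genotypes, np.asarray(depths, dtype=np.int32))


class TestVcfRoundTrip:
    def test_three_variant_fixture(self, tmp_path):
        m = _matrix([[[0, 1], [1, 1]], [[0, 0], [0, 1]], [[1, 1], [-1, -1]]])
        path = tmp_path / "x.vcf"
        write_vcf(path, m)
        records, back = read_vcf(path)
        assert len(records) == 3
        assert [r.position for r in records] == [100, 101, 102]
        np.testing.assert_array_equal(back.genotypes, m.genotypes)
        np.testing.assert_array_equal(back.depths, m.depths)

    def test_vcf_without_dp_keeps_all_after_filter(self, tmp_path):
        path = tmp_path / "nodp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        )
        _, m = read_vcf(path)
        assert m.depths[0, 0] == -1
        kept = filter_by_depth(m, 8)
        np.testing.assert_array_equal(kept.genotypes, m.genotypes)

    def test_multiallelic_site_split(self, tmp_path):
        path = tmp_path / "ma.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG,T\t.\t.\t.\tGT\t1/2\n"
        )
        records, m = read_vcf(path)
        assert [r.alt_allele for r in records] == ["G", "T"]
        # the allele belonging to the other record is recorded as missing
        assert m.genotypes[0, 0].tolist() == [1, -1]
        assert m.genotypes[1, 0].tolist() == [-1, 1]


class TestDepthFilter:
    def test_threshold_boundary(self):
        m = _matrix([[[0, 1], [0, 1], [0, 1]]], depths=[[7, 8, 9]])
        out = filter_by_depth(m, 8)
        assert out.genotypes[0, 0].tolist() == [-1, -1]  # depth 7: dropped
        assert out.genotypes[0, 1].tolist() == [0, 1]  # depth 8: kept
        assert out.genotypes[0, 2].tolist() == [0, 1]

    def test_zero_threshold_is_identity(self):
        m = _matrix([[[0, 1]]], depths=[[2]])
        np.testing.assert_array_equal(filter_by_depth(m, 0).genotypes, m.genotypes)


class TestDecomposeMnp:
    def test_positional_snp_split(self):
        rec = VariantRecord("1", 100, "AT", "GC")
        out = decompose_mnp(rec)
        assert [(v.position, v.ref_allele, v.alt_allele) for v in out] == [
            (100, "A", "G"),
            (101, "T", "C"),
        ]

    def test_shared_flank_trimming(self):
        rec = VariantRecord("1", 50, "CAT", "CGT")
        out = decompose_mnp(rec)
        assert [(v.position, v.ref_allele, v.alt_allele) for v in out] == [(51, "A", "G")]

    def test_insertion_left_aligned_after_trim(self):
        rec = VariantRecord("1", 10, "CA", "CTTA")
        out = decompose_mnp(rec)
        assert len(out) == 1
        v = out[0]
        assert (v.position, v.ref_allele, v.alt_allele) == (10, "C", "CTT")
        assert v.variant_class == "insertion"

    def test_complex_variant_alignment_split(self):
        # substitution plus deletion in one record
        rec = VariantRecord("1", 20, "ACGTACGT", "ACCTACG")
        out = decompose_mnp(rec)
        rebuilt = apply_variants("ACGTACGT", 20, out)
        assert rebuilt == "ACCTACG"
        assert all(v.variant_class in {"SNP", "insertion", "deletion"} for v in out)

    def test_reconstruction_on_random_complex_variants(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            n_ref = int(rng.integers(2, 9))
            n_alt = int(rng.integers(2, 9))
            ref = "".join(rng.choice(bases, n_ref))
            alt = "".join(rng.choice(bases, n_alt))
            if ref == alt:
                continue
            rec = VariantRecord("1", 1000, ref, alt)
            atoms = decompose_mnp(rec)
            assert apply_variants(ref, 1000, atoms) == alt
            for v in atoms:
                assert v.ref_allele != v.alt_allele

    def test_atomic_records_unchanged(self):
        rec = VariantRecord("1", 5, "A", "G")
        assert decompose_mnp(rec) == [rec]

    def test_normalize_trims_trailing_shared_base(self):
        rec = normalize(VariantRecord("1", 7, "ATG", "CG"))
        assert (rec.position, rec.ref_allele, rec.alt_allele) == (7, "AT", "C")


class TestAlleleFrequency:
    def test_single_heterozygote_among_27(self):
        g = [[[0, 0]] * 26 + [[0, 1]]]
        m = _matrix(g)
        freq, display = allele_frequency(m, 0, "ALL")
        assert freq == pytest.approx(1 / 54)
        assert display == 0.02

    def test_all_homozygous_reference(self):
        m = _matrix([[[0, 0]] * 5])
        assert allele_frequency(m, 0)[1] == 0.0

    def test_direct_count(self):
        g = [[[1, 1]] * 3 + [[0, 1]] * 4 + [[0, 0]] * 3]
        m = _matrix(g)
        assert allele_frequency(m, 0)[0] == pytest.approx(0.5)

    def test_missing_calls_excluded_from_denominator(self):
        m = _matrix([[[0, 1], [-1, -1], [0, 0]]])
        freq, _ = allele_frequency(m, 0)
        assert freq == pytest.approx(1 / 4)

    def test_group_with_no_calls_reports_missing(self):
        m = _matrix([[[0, 1], [-1, -1]]], groups=["G1", "G2"])
        assert allele_frequency(m, 0, "G2") == (None, None)

    def test_group_weighted_mean_equals_overall(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, size=(1, 30, 2)).astype(np.int8)
        groups = ["X"] * 10 + ["Y"] * 12 + ["Z"] * 8
        m = _matrix(g, groups=groups)
        total = 0.0
        for name, n in [("X", 10), ("Y", 12), ("Z", 8)]:
            total += allele_frequency(m, 0, name)[0] * n
        assert total / 30 == pytest.approx(allele_frequency(m, 0, "ALL")[0])

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.015) == 0.02
        assert round_half_away(0.0149) == 0.01


class TestClassifyRegion:
    def test_examples(self, toy_model):
        mk = lambda pos: VariantRecord("chrT", pos, "A", "G")  # noqa: E731
        assert classify_region(mk(30), toy_model) == "coding"
        assert classify_region(mk(45), toy_model) == "splice_region"  # 5 bases into intron
        assert classify_region(mk(50), toy_model) == "intron"
        assert classify_region(mk(5), toy_model) == "5_upstream"
        assert classify_region(mk(15), toy_model) == "5utr"
        assert classify_region(mk(85), toy_model) == "3utr"
        assert classify_region(mk(95), toy_model) == "3_downstream"

    def test_one_tag_per_position(self, toy_model):
        valid = {"5_upstream", "5utr", "coding", "intron", "splice_region", "3utr", "3_downstream"}
        for pos in range(1, 101):
            tag = classify_region(VariantRecord("chrT", pos, "A", "G"), toy_model)
            assert tag in valid
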