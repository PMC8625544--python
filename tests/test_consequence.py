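"""Coding consequence prediction, protein-change notation, frameshift arithmetic."""

import numpy as np
import pytest

import oracles
from conftest import TOY_CDS
from milkvar.consequence import (
    flag_splice_region,
    format_protein_change,
    predict_consequence,
    truncated_length,
)
from milkvar.gene_models import TranscriptModel
from milkvar.synthetic_data import synthetic_lgb_model
from milkvar.variant_io import VariantRecord


@pytest.fixture(scope="module")
def lgb():
    return synthetic_lgb_model()


def single_exon_model(cds: str) -> TranscriptModel:
    return TranscriptModel(
        gene_name="ONE",
        transcript_id="ONE-t1",
        chromosome="c",
        strand="+",
        exons=[(1, len(cds))],
        cds_intervals=[(1, len(cds))],
        cds_sequence=cds,
        precursor_offset=0,
        region_start=1,
        region_sequence=cds,
    )


class TestPredictConsequence:
    def test_missense_ala_to_val(self, toy_model):
        # codon 2 GCT -> GTT (CDS position 5, genomic 25)
        rec = VariantRecord("chrT", 25, "C", "T")
        c = predict_consequence(rec, toy_model)
        assert c.kind == "missense"
        assert format_protein_change(c, "precursor") == "p.Ala2Val"

    def test_third_position_wobble_synonymous(self, toy_model):
        # codon 2 GCT -> GCC (CDS position 6, genomic 26)
        rec = VariantRecord("chrT", 26, "T", "C")
        c = predict_consequence(rec, toy_model)
        assert c.kind == "synonymous"
        assert format_protein_change(c, "precursor") == "p.Ala2"

    def test_stop_gained(self, toy_model):
        # codon 6 CAT -> TAT? no; make CAT -> TAA impossible with one base.
        # codon 11 AGC: CDS pos 31 A->T gives TGC (Cys) missense; use codon
        # 3 GAA -> TAA via CDS pos 7 (genomic 27) G->T
        rec = VariantRecord("chrT", 27, "G", "T")
        c = predict_consequence(rec, toy_model)
        assert c.kind == "stop_gained"
        assert format_protein_change(c, "precursor") == "p.Glu3*"

    def test_reverse_strand_gives_same_call(self, toy_model, toy_model_rev):
        # the same CDS change seen from the reverse-complemented contig:
        # plus-model genomic 25 C>T maps to minus-model genomic 101-25=76 G>A
        plus = predict_consequence(VariantRecord("chrT", 25, "C", "T"), toy_model)
        minus = predict_consequence(VariantRecord("chrT", 76, "G", "A"), toy_model_rev)
        assert (plus.kind, plus.precursor_change) == (minus.kind, minus.precursor_change)

    def test_reference_mismatch_is_hard_error(self, toy_model):
        with pytest.raises(ValueError, match="mismatch"):
            predict_consequence(VariantRecord("chrT", 25, "G", "T"), toy_model)

    def test_non_coding_position_rejected(self, toy_model):
        with pytest.raises(ValueError, match="intron"):
            predict_consequence(VariantRecord("chrT", 50, "A", "G"), toy_model)

    def test_random_indels_match_mutate_and_translate_oracle(self):
        rng = np.random.default_rng(17)
        safe = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in {"TAA", "TAG", "TGA"}
        ]
        cds = "ATG" + "".join(rng.choice(safe, 60)) + "TAA"
        model = single_exon_model(cds)
        n_checked = 0
        while n_checked < 50:
            pos0 = int(rng.integers(3, len(cds) - 6))
            if rng.random() < 0.5:  # single-base insertion
                ref = cds[pos0]
                alt = ref + str(rng.choice(list("ACGT")))
            else:  # single-base deletion
                ref = cds[pos0 : pos0 + 2]
                alt = cds[pos0]
            kind, first, terminal = oracles.indel_consequence(cds, pos0, ref, alt)
            rec = VariantRecord("c", pos0 + 1, ref, alt)
            c = predict_consequence(rec, model)
            assert c.kind == kind
            if kind == "frameshift" and terminal is not None:
                assert (c.precursor_position, c.terminal_offset) == (first, terminal)
                assert not c.no_stop
            n_checked += 1


class TestLgbFrameshift:
    """The beta-lactoglobulin adenine insertion worked example."""

    def test_notation_and_truncation(self, lgb):
        rec = VariantRecord("11", 103257980, "A", "AA", "ss7626433430")
        c = predict_consequence(rec, lgb)
        assert c.kind == "frameshift"
        assert format_protein_change(c, "mature") == "p.Thr92Asnfs*13"
        assert format_protein_change(c, "precursor") == "p.Thr108Asnfs*13"
        assert truncated_length(c, "mature") == 104
        # product is 74 residues shorter than the 178-residue precursor
        assert lgb.precursor_length == 178
        assert lgb.precursor_length - truncated_length(c, "mature") == 74

    def test_insertion_lands_in_exon_3(self, lgb):
        assert lgb.exon_number(103257980) == 3

    def test_synonymous_neighbour_notation(self, lgb):
        # the synonymous site at mature Asn88 (precursor 104, codon AAT>AAC)
        from milkvar.gene_models import cds_to_genomic

        pos = cds_to_genomic(lgb, 104 * 3)  # third base of codon 104
        rec = VariantRecord("11", pos, "T", "C")
        c = predict_consequence(rec, lgb)
        assert c.kind == "synonymous"
        assert format_protein_change(c, "mature") == "p.Asn88"

    def test_missense_b1_notation(self, lgb):
        from milkvar.gene_models import cds_to_genomic

        pos = cds_to_genomic(lgb, (134 - 1) * 3 + 2)  # codon 134 second base
        assert pos == 103259232
        rec = VariantRecord("11", pos, "C", "T")
        c = predict_consequence(rec, lgb)
        assert format_protein_change(c, "mature") == "p.Ala118Val"


class TestTruncatedLength:
    def test_published_arithmetic(self):
        from milkvar.consequence import ConsequenceRecord

        c = ConsequenceRecord(
            variant=VariantRecord("11", 1, "A", "AA"),
            gene_name="LGB",
            transcript_id="t",
            kind="frameshift",
            ref_residue="T",
            alt_residue="N",
            precursor_position=108,
            terminal_offset=13,
            precursor_offset=16,
        )
        assert truncated_length(c, "mature") == 104
        c2 = ConsequenceRecord(
            variant=c.variant,
            gene_name="X",
            transcript_id="t",
            kind="frameshift",
            ref_residue="M",
            alt_residue="K",
            precursor_position=1,
            terminal_offset=1,
            precursor_offset=0,
        )
        assert truncated_length(c2, "precursor") == 1

    def test_no_stop_flag(self):
        from milkvar.consequence import ConsequenceRecord

        c = ConsequenceRecord(
            variant=VariantRecord("1", 1, "A", "AT"),
            gene_name="X",
            transcript_id="t",
            kind="frameshift",
            ref_residue="A",
            alt_residue="S",
            precursor_position=5,
            terminal_offset=3,
            no_stop=True,
        )
        assert truncated_length(c) == "no-stop"

    def test_rejects_non_frameshift(self, toy_model):
        c = predict_consequence(VariantRecord("chrT", 25, "C", "T"), toy_model)
        with pytest.raises(ValueError):
            truncated_length(c)


class TestFormatProteinChange:
    def test_mature_within_signal_peptide(self):
        from milkvar.consequence import ConsequenceRecord

        c = ConsequenceRecord(
            variant=VariantRecord("6", 1, "C", "T"),
            gene_name="CSN2",
            transcript_id="t",
            kind="synonymous",
            ref_residue="A",
            alt_residue="",
            precursor_position=42,
            precursor_offset=50,
        )
        assert format_protein_change(c, "precursor") == "p.Ala42"
        assert format_protein_change(c, "mature") == "pre-mature region"


class TestSpliceRegionFlag:
    def test_examples(self, toy_model):
        assert flag_splice_region(VariantRecord("chrT", 42, "A", "G"), toy_model)
        assert not flag_splice_region(VariantRecord("chrT", 30, "A", "G"), toy_model)

    def test_window_sweep_matches_distance_rule(self, toy_model):
        # brute force: distance of each position to the two junctions
        donor_end, acceptor_start = 40, 61  # exon1 end, exon2 start
        for pos in range(1, 101):
            in_exon = 11 <= pos <= 40 or 61 <= pos <= 90
            if in_exon:
                expected = donor_end - 2 <= pos <= donor_end or acceptor_start <= pos <= acceptor_start + 2
            else:
                expected = (
                    donor_end + 1 <= pos <= donor_end + 8
                    or acceptor_start - 8 <= pos <= acceptor_start - 1
                ) and 41 <= pos <= 60
            got = flag_splice_region(VariantRecord("chrT", pos, "A", "G"), toy_model)
            assert got == expected, pos
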