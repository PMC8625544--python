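"""Shared fixtures: hand-built toy transcript models and the synthetic bundle."""

import pytest

from milkvar.gene_models import TranscriptModel
from milkvar.synthetic_data import SimConfig, generate_cohort, generate_reference

# Toy 2-exon gene, hand-spliced.  Contig layout (1-based):
#   1-10    leading pad
#   11-40   exon 1  (11-20 5'UTR, 21-40 CDS part 1)
#   41-60   intron  (GT...AG)
#   61-90   exon 2  (61-82 CDS part 2, 83-90 3'UTR)
#   91-100  trailing pad
TOY_CDS = "ATGGCTGAATTCGGGCATACACCATTGGTCAGCAAAGATTAA"  # 14 codons
TOY_CDS1 = TOY_CDS[:20]
TOY_CDS2 = TOY_CDS[20:]
TOY_GENOME = (
    "CCCCCCCCCC"  # 1-10
    + "TTTTTTTTTT"  # 11-20 5'UTR
    + TOY_CDS1  # 21-40
    + "GTAAACCCGGGTTTACCAAG"  # 41-60 intron
    + TOY_CDS2  # 61-82
    + "AAAAAAAA"  # 83-90 3'UTR
    + "CCCCCCCCCC"  # 91-100
)
assert len(TOY_GENOME) == 100

TOY_PROTEIN = "MAEFGHTPLVSKD"  # translation of TOY_CDS without the stop


def build_toy_model(strand: str = "+") -> TranscriptModel:
    """The toy gene as a TranscriptModel; '-' places it on the reverse strand
    of the reverse-complemented contig (same transcript content)."""
    if strand == "+":
        return TranscriptModel(
            gene_name="TOY",
            transcript_id="TOY-t1",
            chromosome="chrT",
            strand="+",
            exons=[(11, 40), (61, 90)],
            cds_intervals=[(21, 40), (61, 82)],
            cds_sequence=TOY_CDS,
            precursor_offset=3,
            region_start=1,
            region_sequence=TOY_GENOME,
        )
    from Bio.Seq import Seq

    rc = str(Seq(TOY_GENOME).reverse_complement())
    flip = lambda s, e: (101 - e, 101 - s)  # noqa: E731
    return TranscriptModel(
        gene_name="TOY",
        transcript_id="TOY-t1r",
        chromosome="chrT",
        strand="-",
        exons=[flip(11, 40), flip(61, 90)],
        cds_intervals=[flip(21, 40), flip(61, 82)],
        cds_sequence=TOY_CDS,
        precursor_offset=3,
        region_start=1,
        region_sequence=rc,
    )


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model("+")


@pytest.fixture(scope="session")
def toy_model_rev():
    return build_toy_model("-")


@pytest.fixture(scope="session")
def toy_gff3_fasta(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    fasta = d / "toy.fa"
    fasta.write_text(">chrT\n" + TOY_GENOME + "\n")
    gff = d / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chrT\ttest\tgene\t11\t90\t.\t+\t.\tID=gene-TOY;Name=TOY\n"
        "chrT\ttest\tmRNA\t11\t90\t.\t+\t.\tID=TOY-t1;Parent=gene-TOY\n"
        "chrT\ttest\texon\t11\t40\t.\t+\t.\tID=e1;Parent=TOY-t1\n"
        "chrT\ttest\texon\t61\t90\t.\t+\t.\tID=e2;Parent=TOY-t1\n"
        "chrT\ttest\tCDS\t21\t40\t.\t+\t0\tID=c1;Parent=TOY-t1\n"
        "chrT\ttest\tCDS\t61\t82\t.\t+\t0\tID=c2;Parent=TOY-t1\n"
    )
    return gff, fasta


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """One deterministic reference + cohort shared by the whole suite."""
    d = tmp_path_factory.mktemp("synth")
    config = SimConfig(seed=11, depth_range=(8, 60))  # no depth-filter losses
    reference = generate_reference(config, d)
    cohort = generate_cohort(reference, d)
    return reference, cohort


@pytest.fixture(scope="session")
def synthetic_models(synthetic_bundle):
    from milkvar.gene_models import OffsetConfig, load_transcripts

    reference, _ = synthetic_bundle
    models = load_transcripts(
        reference.gff3_path,
        reference.fasta_path,
        offsets=OffsetConfig(reference.offsets),
        transcript_ids=reference.transcript_ids,
    )
    return {m.gene_name: m for m in models}
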