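"""Transcript models and coordinate arithmetic for milk protein genes.

This module owns every conversion between genomic, coding-sequence (CDS) and
protein coordinates, including reverse-strand handling and the conversion
between precursor (signal peptide included) and mature protein residue
numbering that milk protein nomenclature is written in.

Coordinates are 1-based, closed intervals throughout (GFF3/VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "OffsetConfig",
    "TABLE_OFFSETS",
    "CANONICAL_OFFSETS",
    "PRE_MATURE",
    "load_transcripts",
    "genomic_to_cds",
    "cds_to_genomic",
    "cds_to_protein",
    "precursor_to_mature",
]

#: Tag returned for residues that fall inside the signal peptide.
PRE_MATURE = "pre-mature region"

#: Default flank (bp) beyond which positions are upstream/downstream.
DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class OffsetConfig:
    """Per-gene residues to subtract when converting precursor to mature numbering.

    The signal peptide of each milk protein is cleaved from the translation
    product; published allele nomenclature numbers residues in the mature,
    secreted protein.
    """

    offsets: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> int:
        try:
            return self.offsets[gene]
        except KeyError:
            raise KeyError(f"no precursor offset configured for gene {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self.offsets


#: Offsets implied by the printed mature/(precursor) residue pairs of the
#: milk protein allele nomenclature tables (the package default).
TABLE_OFFSETS = OffsetConfig(
    {"CSN1S1": 15, "CSN2": 50, "CSN1S2": 15, "CSN3": 21, "LALBA": 48, "LGB": 16}
)

#: Alternative config with the canonical signal-peptide lengths.  CSN2 and
#: LALBA differ from the table-derived values (15 vs 50, 19 vs 48); both
#: conventions circulate, so both configs ship.
CANONICAL_OFFSETS = OffsetConfig(
    {"CSN1S1": 15, "CSN2": 15, "CSN1S2": 15, "CSN3": 21, "LALBA": 19, "LGB": 16}
)


@dataclass
class TranscriptModel:
    """One selected transcript of a gene with its spliced CDS.

    ``exons`` and ``cds_intervals`` are lists of genomic ``(start, end)``
    pairs (1-based, closed, start <= end) ordered in *transcription* order:
    ascending genomic coordinate on the plus strand, descending on the minus
    strand.  ``cds_sequence`` is the spliced, strand-corrected coding
    sequence (starts with the initiator codon, ends with the stop codon).

    ``region_sequence`` holds the plus-strand genomic sequence of a window
    around the transcript (``region_start`` is the genomic coordinate of its
    first base) so that UTR/flank sequence can be extracted without a genome
    on disk.
    """

    gene_name: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    cds_sequence: str
    precursor_offset: int
    region_start: int = 1
    region_sequence: str = ""
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"CDS length of transcript {self.transcript_id} "
                f"({len(self.cds_sequence)}) is not a multiple of 3"
            )

    # -- geometry helpers -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min, max) over all exons."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def precursor_length(self) -> int:
        """Precursor protein length in residues (stop codon excluded)."""
        return self.cds_length // 3 - 1

    def region_base(self, pos: int) -> str:
        """Plus-strand base at genomic position ``pos`` from the cached window."""
        idx = pos - self.region_start
        if idx < 0 or idx >= len(self.region_sequence):
            raise IndexError(
                f"position {self.chromosome}:{pos} outside cached region of "
                f"{self.transcript_id}"
            )
        return self.region_sequence[idx]

    def region_slice(self, start: int, end: int) -> str:
        """Plus-strand sequence of genomic [start, end] (1-based closed)."""
        i, j = start - self.region_start, end - self.region_start + 1
        if i < 0 or j > len(self.region_sequence):
            raise IndexError(
                f"interval {self.chromosome}:{start}-{end} outside cached region"
            )
        return self.region_sequence[i:j]

    def exon_number(self, pos: int) -> int | None:
        """1-based exon number (transcription order) containing ``pos``."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _transcription_sorted(
    intervals: Iterable[tuple[int, int]], strand: str
) -> list[tuple[int, int]]:
    return sorted(intervals, key=lambda iv: iv[0], reverse=(strand == "-"))


def load_transcripts(
    gff3_path,
    fasta_path,
    offsets: OffsetConfig = TABLE_OFFSETS,
    transcript_ids: dict[str, str] | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[TranscriptModel]:
    """Load one transcript model per gene from a GFF3 and genome FASTA.

    ``transcript_ids`` maps gene name -> transcript ID; for genes not listed
    (or when ``None``) the first mRNA of the gene is used.  The spliced CDS is
    reverse-complemented for minus-strand genes so that ``cds_sequence``
    always reads in translation order.

    Raises ``ValueError`` if the GFF3 holds no transcripts, if a requested
    transcript ID is absent, or if a CDS length is not a multiple of 3.
    """
    import gffutils
    from pyfaidx import Fasta

    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        raise ValueError(f"no transcripts found in {gff3_path}") from None
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    mrnas = list(db.features_of_type(("mRNA", "transcript")))
    if not mrnas:
        raise ValueError(f"no transcripts found in {gff3_path}")

    by_gene: dict[str, list] = {}
    for mrna in mrnas:
        gene_name = _gene_name_of(db, mrna)
        by_gene.setdefault(gene_name, []).append(mrna)

    requested = dict(transcript_ids or {})
    models: list[TranscriptModel] = []
    for gene_name, candidates in by_gene.items():
        if gene_name in requested:
            want = requested.pop(gene_name)
            chosen = next((m for m in candidates if m.id == want), None)
            if chosen is None:
                raise ValueError(
                    f"transcript {want!r} for gene {gene_name!r} not in GFF3"
                )
        else:
            chosen = candidates[0]
        models.append(_build_model(db, fasta, gene_name, chosen, offsets, flank))

    if requested:
        missing = ", ".join(f"{g}:{t}" for g, t in requested.items())
        raise ValueError(f"requested transcripts not found: {missing}")
    return models


def _gene_name_of(db, mrna) -> str:
    for parent in db.parents(mrna, featuretype="gene"):
        for key in ("Name", "gene_name", "ID"):
            if key in parent.attributes:
                return parent.attributes[key][0]
    for key in ("gene", "gene_name"):
        if key in mrna.attributes:
            return mrna.attributes[key][0]
    return mrna.id


def _build_model(db, fasta, gene_name, mrna, offsets, flank) -> TranscriptModel:
    strand = mrna.strand
    exons = _transcription_sorted(
        [(f.start, f.end) for f in db.children(mrna, featuretype="exon")], strand
    )
    cds = _transcription_sorted(
        [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")], strand
    )
    if not exons:
        # permit exon-less annotations where CDS features double as exons
        exons = list(cds)
    if not cds:
        raise ValueError(f"transcript {mrna.id} has no CDS features")

    plus_seq = "".join(
        fasta[mrna.seqid][s - 1 : e] for s, e in sorted(cds, key=lambda iv: iv[0])
    )
    cds_sequence = _revcomp(plus_seq) if strand == "-" else plus_seq
    if len(cds_sequence) % 3 != 0:
        raise ValueError(
            f"CDS length of transcript {mrna.id} ({len(cds_sequence)}) "
            "is not a multiple of 3"
        )

    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    contig_len = len(fasta[mrna.seqid][:])
    win_lo = max(1, lo - flank)
    win_hi = min(contig_len, hi + flank)
    region_sequence = fasta[mrna.seqid][win_lo - 1 : win_hi]

    offset = offsets[gene_name] if gene_name in offsets else 0
    return TranscriptModel(
        gene_name=gene_name,
        transcript_id=mrna.id,
        chromosome=mrna.seqid,
        strand=strand,
        exons=exons,
        cds_intervals=cds,
        cds_sequence=cds_sequence,
        precursor_offset=offset,
        region_start=win_lo,
        region_sequence=region_sequence,
        flank=flank,
    )


# -- genomic <-> CDS ------------------------------------------------------


def genomic_to_cds(model: TranscriptModel, genomic_pos: int):
    """Map a genomic position to a 1-based CDS position or a region tag.

    Returns an ``int`` for positions inside the CDS (counting along the
    spliced coding sequence in translation order, strand-aware), otherwise
    one of the tags ``upstream``, ``5utr``, ``intron``, ``3utr``,
    ``downstream`` relative to the direction of transcription.
    """
    if genomic_pos < 1:
        raise ValueError("genomic position must be positive")

    # inside CDS?
    consumed = 0
    for s, e in model.cds_intervals:
        if s <= genomic_pos <= e:
            if model.strand == "+":
                return consumed + (genomic_pos - s) + 1
            return consumed + (e - genomic_pos) + 1
        consumed += e - s + 1

    lo, hi = model.span
    before = genomic_pos < lo  # genomically before the transcript
    after = genomic_pos > hi
    if before or after:
        upstream_genomically = before if model.strand == "+" else after
        return "upstream" if upstream_genomically else "downstream"

    in_exon = any(s <= genomic_pos <= e for s, e in model.exons)
    if not in_exon:
        return "intron"

    # exonic but non-coding: 5' or 3' UTR depending on transcription direction
    cds_lo = min(s for s, _ in model.cds_intervals)
    cds_hi = max(e for _, e in model.cds_intervals)
    if model.strand == "+":
        return "5utr" if genomic_pos < cds_lo else "3utr"
    return "5utr" if genomic_pos > cds_hi else "3utr"


def cds_to_genomic(model: TranscriptModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` for coding positions."""
    if not 1 <= cds_pos <= model.cds_length:
        raise ValueError(
            f"CDS position {cds_pos} out of range 1..{model.cds_length}"
        )
    remaining = cds_pos
    for s, e in model.cds_intervals:
        size = e - s + 1
        if remaining <= size:
            if model.strand == "+":
                return s + remaining - 1
            return e - remaining + 1
        remaining -= size
    raise AssertionError("unreachable")


def cds_to_protein(cds_pos: int, cds_length: int | None = None) -> tuple[int, int]:
    """Return ``(precursor_residue, codon_offset)`` for a CDS position.

    ``precursor_residue`` is ceil(cds_pos / 3); ``codon_offset`` is the
    0-based position within the codon.
    """
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    if cds_length is not None and cds_pos > cds_length:
        raise ValueError(f"CDS position {cds_pos} beyond CDS length {cds_length}")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3


def precursor_to_mature(
    gene: str, precursor_residue: int, offsets: OffsetConfig = TABLE_OFFSETS
):
    """Convert a precursor residue number to mature numbering.

    Returns the mature residue (``precursor - offset``) when positive, else
    the tag :data:`PRE_MATURE` for residues inside the signal peptide.
    """
    offset = offsets[gene]
    mature = precursor_residue - offset
    return mature if mature > 0 else PRE_MATURE
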