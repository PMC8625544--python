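"""Protein-consequence prediction with precursor and mature numbering.

Coding variants are applied to the spliced CDS, the reference and alternate
products are translated with the standard genetic code, and the change is
reported in HGVS-style notation twice: against the precursor (signal
peptide included) and against the mature protein, the numbering milk
protein allele nomenclature uses.

Frameshift notation follows the convention of the milk protein literature:
``p.Xaa<n>Yaafs*<m>`` where ``m`` counts the changed residues from the
first changed one (as 1) through the last residue before the novel stop,
so the stop codon itself sits at new-frame position ``m + 1`` and the
truncated product ends at residue ``n + m - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .gene_models import (
    PRE_MATURE,
    TranscriptModel,
    cds_to_protein,
    genomic_to_cds,
    precursor_to_mature,
)
from .variant_io import VariantRecord, classify_region

__all__ = [
    "ConsequenceRecord",
    "predict_consequence",
    "format_protein_change",
    "truncated_length",
    "flag_splice_region",
]

_STOP = "*"


@dataclass
class ConsequenceRecord:
    """Predicted effect of one coding variant on one transcript."""

    variant: VariantRecord
    gene_name: str
    transcript_id: str
    kind: str  # synonymous | missense | stop_gained | frameshift | inframe_indel
    ref_residue: str  # 1-letter code of the (first changed) reference residue
    alt_residue: str  # 1-letter code after the change ("" for synonymous)
    precursor_position: int  # first changed (or affected) residue, precursor numbering
    terminal_offset: int | None = None  # frameshift: changed residues incl. first
    no_stop: bool = False  # frameshift never reached a stop codon
    precursor_offset: int = 0

    @property
    def mature_position(self):
        return self.precursor_position - self.precursor_offset \
            if self.precursor_position > self.precursor_offset else PRE_MATURE

    @property
    def precursor_change(self) -> str:
        return format_protein_change(self, "precursor")

    @property
    def mature_change(self) -> str:
        return format_protein_change(self, "mature")


def _translate(cds: str, through_stop: bool = False) -> str:
    """Translate, either the whole (in-frame) sequence or up to first stop."""
    usable = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(usable).translate())
    if through_stop:
        stop = prot.find(_STOP)
        if stop >= 0:
            return prot[: stop + 1]
        return prot
    return prot


def _alt_cds(model: TranscriptModel, record: VariantRecord) -> str:
    """Spliced CDS (plus downstream exonic sequence) with the variant applied.

    The variant must be contained in a single CDS interval.  Editing is done
    on the plus-strand spliced sequence and re-oriented afterwards, so
    reverse-strand genes need no special casing at the call site.
    """
    plus_intervals = sorted(model.cds_intervals)
    plus_cds = []
    offsets = {}
    consumed = 0
    for s, e in plus_intervals:
        offsets[(s, e)] = consumed
        consumed += e - s + 1
    # plus-strand spliced CDS straight from the strand-corrected sequence
    plus_seq = (
        str(Seq(model.cds_sequence).reverse_complement())
        if model.strand == "-"
        else model.cds_sequence
    )

    home = None
    for s, e in plus_intervals:
        if s <= record.position <= e:
            if record.end > e:
                raise ValueError(
                    "variant spans a CDS interval boundary; not supported"
                )
            home = (s, e)
            break
    if home is None:
        raise ValueError("variant does not fall in the CDS")

    idx = offsets[home] + (record.position - home[0])
    observed = plus_seq[idx : idx + len(record.ref_allele)]
    if observed != record.ref_allele.upper():
        raise ValueError(
            f"reference allele mismatch at {record.chromosome}:{record.position}: "
            f"VCF says {record.ref_allele!r}, transcript {model.transcript_id} "
            f"has {observed!r}"
        )
    edited = plus_seq[:idx] + record.alt_allele.upper() + plus_seq[idx + len(record.ref_allele) :]
    if model.strand == "-":
        edited = str(Seq(edited).reverse_complement())
    # frameshifted products may run past the original stop; append 3'UTR
    # exonic sequence (in transcription order) when the model carries it
    edited += _downstream_exonic(model)
    return edited


def _downstream_exonic(model: TranscriptModel) -> str:
    if not model.region_sequence:
        return ""
    if model.strand == "+":
        cds_hi = max(e for _, e in model.cds_intervals)
        chunks = []
        for s, e in sorted(model.exons):
            if e > cds_hi:
                lo = max(s, cds_hi + 1)
                try:
                    chunks.append(model.region_slice(lo, e))
                except IndexError:
                    break
        return "".join(chunks)
    cds_lo = min(s for s, _ in model.cds_intervals)
    chunks = []
    for s, e in sorted(model.exons, reverse=True):
        if s < cds_lo:
            hi = min(e, cds_lo - 1)
            try:
                chunks.append(str(Seq(model.region_slice(s, hi)).reverse_complement()))
            except IndexError:
                break
    return "".join(chunks)


def predict_consequence(record: VariantRecord, model: TranscriptModel) -> ConsequenceRecord:
    """Predict the coding consequence of a variant on a transcript.

    The variant must fall in the CDS.  SNP/MNP records compare the in-frame
    translations; InDels whose length difference is not a multiple of 3 are
    frameshifts, translated through the first stop codon in the new frame.
    """
    cds_tag = genomic_to_cds(model, record.position)
    if not isinstance(cds_tag, int):
        raise ValueError(
            f"variant {record.chromosome}:{record.position} is {cds_tag}, not coding"
        )
    ref_prot = _translate(model.cds_sequence)  # includes terminal '*'
    alt_cds = _alt_cds(model, record)
    length_delta = len(record.alt_allele) - len(record.ref_allele)

    common = dict(
        variant=record,
        gene_name=model.gene_name,
        transcript_id=model.transcript_id,
        precursor_offset=model.precursor_offset,
    )

    if length_delta % 3 != 0:
        alt_prot = _translate(alt_cds, through_stop=True)
        first = _first_difference(ref_prot, alt_prot)
        if first is None:  # changed bases but identical product up to stop
            first = min(len(ref_prot), len(alt_prot)) - 1
        stop_idx = alt_prot.find(_STOP)
        no_stop = stop_idx < 0
        if stop_idx == first:
            # the shifted frame opens directly on a stop codon: a nonsense
            # change, written p.Xaa<n>* rather than fs notation
            return ConsequenceRecord(
                kind="stop_gained",
                ref_residue=ref_prot[first],
                alt_residue=_STOP,
                precursor_position=first + 1,
                **common,
            )
        terminal = (stop_idx - first) if not no_stop else (len(alt_prot) - first)
        return ConsequenceRecord(
            kind="frameshift",
            ref_residue=ref_prot[first],
            alt_residue=alt_prot[first] if first < len(alt_prot) else "",
            precursor_position=first + 1,
            terminal_offset=max(int(terminal), 1),
            no_stop=no_stop,
            **common,
        )

    alt_prot = _translate(alt_cds, through_stop=True)
    if length_delta == 0:
        if alt_prot.rstrip(_STOP) == ref_prot.rstrip(_STOP) and len(alt_prot) >= len(
            ref_prot.rstrip(_STOP)
        ):
            # same product: synonymous; report the residue the codon encodes
            residue, _ = cds_to_protein(cds_tag, model.cds_length)
            return ConsequenceRecord(
                kind="synonymous",
                ref_residue=ref_prot[residue - 1],
                alt_residue="",
                precursor_position=residue,
                **common,
            )
        first = _first_difference(ref_prot, alt_prot)
        assert first is not None
        new = alt_prot[first] if first < len(alt_prot) else ""
        if new == _STOP:
            return ConsequenceRecord(
                kind="stop_gained",
                ref_residue=ref_prot[first],
                alt_residue=_STOP,
                precursor_position=first + 1,
                **common,
            )
        return ConsequenceRecord(
            kind="missense",
            ref_residue=ref_prot[first],
            alt_residue=new,
            precursor_position=first + 1,
            **common,
        )

    # in-frame indel
    first = _first_difference(ref_prot, alt_prot)
    if first is None:
        first = (cds_tag + 2) // 3 - 1
    return ConsequenceRecord(
        kind="inframe_indel",
        ref_residue=ref_prot[first] if first < len(ref_prot) else "",
        alt_residue=alt_prot[first] if first < len(alt_prot) else "",
        precursor_position=first + 1,
        **common,
    )


def _first_difference(a: str, b: str) -> int | None:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    if len(a) != len(b):
        return min(len(a), len(b))
    return None


def _aa3(one_letter: str) -> str:
    return "*" if one_letter == _STOP else seq3(one_letter)


def format_protein_change(c: ConsequenceRecord, numbering: str = "mature") -> str:
    """HGVS-style protein notation in precursor or mature numbering.

    Missense ``p.Ala66Val``; synonymous ``p.Asn88``; stop gained
    ``p.Gln10*``; frameshift ``p.Thr92Asnfs*13``.  Residues inside the
    signal peptide have no mature coordinate and return the tag
    ``pre-mature region`` when mature numbering is requested.
    """
    if numbering not in {"precursor", "mature"}:
        raise ValueError(f"unknown numbering {numbering!r}")
    if c.kind == "non_coding":
        raise ValueError("cannot format a non-coding record as a protein change")
    if numbering == "mature":
        pos = c.mature_position
        if pos == PRE_MATURE:
            return PRE_MATURE
    else:
        pos = c.precursor_position

    ref3 = _aa3(c.ref_residue)
    if c.kind == "synonymous":
        return f"p.{ref3}{pos}"
    if c.kind == "missense":
        return f"p.{ref3}{pos}{_aa3(c.alt_residue)}"
    if c.kind == "stop_gained":
        return f"p.{ref3}{pos}*"
    if c.kind == "frameshift":
        if c.no_stop:
            return f"p.{ref3}{pos}{_aa3(c.alt_residue)}fs*?"
        return f"p.{ref3}{pos}{_aa3(c.alt_residue)}fs*{c.terminal_offset}"
    if c.kind == "inframe_indel":
        return f"p.{ref3}{pos}delins{_aa3(c.alt_residue) if c.alt_residue else ''}"
    raise ValueError(f"unknown consequence kind {c.kind!r}")


def truncated_length(c: ConsequenceRecord, numbering: str = "mature"):
    """Position of the last residue before a frameshift's novel stop codon.

    ``first_changed_residue + terminal_offset - 1`` in the requested
    numbering.  Returns the string ``"no-stop"`` if the new reading frame
    never reached a stop codon.
    """
    if c.kind != "frameshift":
        raise ValueError("truncated_length is defined for frameshift records only")
    if c.no_stop:
        return "no-stop"
    first = c.mature_position if numbering == "mature" else c.precursor_position
    if first == PRE_MATURE:
        raise ValueError("frameshift starts in the signal peptide; use precursor numbering")
    return first + c.terminal_offset - 1


def flag_splice_region(
    record: VariantRecord,
    model: TranscriptModel,
    donor_window: int = 8,
    acceptor_window: int = 8,
    exonic_window: int = 3,
) -> bool:
    """True iff the variant lies within the configured splice-junction windows.

    ``donor_window``/``acceptor_window`` count bases into the intron from
    the donor (5') and acceptor (3') side of each junction; ``exonic_window``
    counts bases into the exon from either side.
    """
    pos = record.position
    lo, hi = model.span
    if not lo <= pos <= hi:
        return False
    sorted_exons = sorted(model.exons)
    in_exon = any(s <= pos <= e for s, e in model.exons)
    for i, (s, e) in enumerate(sorted_exons):
        has_intron_left = i > 0
        has_intron_right = i < len(sorted_exons) - 1
        # windows are symmetric in genomic space; donor vs acceptor side
        # depends on strand
        if has_intron_right:
            intron_win = donor_window if model.strand == "+" else acceptor_window
            if in_exon and e - exonic_window + 1 <= pos <= e:
                return True
            if not in_exon and e + 1 <= pos <= e + intron_win:
                return True
        if has_intron_left:
            intron_win = acceptor_window if model.strand == "+" else donor_window
            if in_exon and s <= pos <= s + exonic_window - 1:
                return True
            if not in_exon and s - intron_win <= pos <= s - 1:
                return True
    return False
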