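"""VCF input/output, variant normalization, depth filtering and allele frequencies.

The pipeline starts at called variants: this module reads diploid genotypes
with per-call depth from VCF 4.x, splits multi-allelic sites, decomposes
multi-nucleotide/complex records into atomic SNPs and InDels, applies the
minimum-coverage filter, and computes per-breed allele frequencies.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .gene_models import TranscriptModel, genomic_to_cds

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_groups",
    "filter_by_depth",
    "normalize",
    "decompose_mnp",
    "allele_frequency",
    "classify_region",
]

MIN_DEPTH_DEFAULT = 8  # calls below this read coverage are set to missing


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic, normalized variant."""

    chromosome: str
    position: int  # 1-based; for InDels the anchor base before the event
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def variant_class(self) -> str:
        r, a = len(self.ref_allele), len(self.alt_allele)
        if r == a:
            return "SNP" if r == 1 else "MNP"
        return "insertion" if a > r else "deletion"

    @property
    def is_indel(self) -> bool:
        return self.variant_class in {"insertion", "deletion"}

    @property
    def end(self) -> int:
        """Last reference base touched (== position for SNPs/insertions)."""
        return self.position + len(self.ref_allele) - 1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes with per-call depth and group labels.

    ``genotypes`` has shape (n_variants, n_animals, 2) with allele indices
    0 (ref) / 1 (alt) and -1 for missing; ``depths`` has shape
    (n_variants, n_animals) with -1 when depth is unknown.
    """

    variants: list[VariantRecord]
    animals: list[tuple[str, str]]  # (animal id, group label)
    genotypes: np.ndarray
    depths: np.ndarray

    def __post_init__(self):
        n_v, n_a = len(self.variants), len(self.animals)
        assert self.genotypes.shape == (n_v, n_a, 2)
        assert self.depths.shape == (n_v, n_a)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, g in self.animals:
            seen.setdefault(g)
        return list(seen)

    def group_indices(self, group: str | None) -> np.ndarray:
        """Column indices of a group, or all columns for ``None``/"ALL"."""
        if group is None or group == "ALL":
            return np.arange(self.n_animals)
        idx = np.array([i for i, (_, g) in enumerate(self.animals) if g == group])
        if idx.size == 0:
            raise KeyError(f"no animals in group {group!r}")
        return idx

    def variant_index(self, chromosome: str, position: int, alt: str | None = None) -> int:
        for i, v in enumerate(self.variants):
            if v.chromosome == chromosome and v.position == position:
                if alt is None or v.alt_allele == alt:
                    return i
        raise KeyError(f"variant {chromosome}:{position} not in matrix")


# -- VCF I/O ---------------------------------------------------------------


def read_vcf(path, groups: dict[str, str] | None = None):
    """Read a VCF into ``(records, GenotypeMatrix)``.

    Multi-allelic sites are split into bi-allelic records (a genotype allele
    belonging to another alternate is recorded as missing for that record).
    ``groups`` maps animal id -> group label; unlisted animals get "ALL".
    """
    import pysam

    groups = groups or {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        animals = [(s, groups.get(s, "ALL")) for s in samples]
        records: list[VariantRecord] = []
        gts: list[np.ndarray] = []
        dps: list[np.ndarray] = []
        for line_no, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                for alt_i, alt in enumerate(alts, start=1):
                    records.append(
                        VariantRecord(
                            chromosome=rec.contig,
                            position=rec.pos,
                            ref_allele=rec.ref,
                            alt_allele=alt,
                            id=rec.id or ".",
                        )
                    )
                    g = np.full((len(samples), 2), -1, dtype=np.int8)
                    d = np.full(len(samples), -1, dtype=np.int32)
                    for j, s in enumerate(samples):
                        call = rec.samples[s]
                        alleles = call.get("GT") or (None, None)
                        if len(alleles) == 1:
                            alleles = (alleles[0], alleles[0])
                        for k, a in enumerate(alleles[:2]):
                            if a is None:
                                g[j, k] = -1
                            elif a == 0:
                                g[j, k] = 0
                            elif a == alt_i:
                                g[j, k] = 1
                            else:  # allele of a different alternate
                                g[j, k] = -1
                        dp = call.get("DP")
                        d[j] = dp if dp is not None else -1
                    gts.append(g)
                    dps.append(d)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(f"malformed VCF record at line ~{line_no}: {exc}") from exc

    genotypes = np.stack(gts) if gts else np.empty((0, len(samples), 2), dtype=np.int8)
    depths = np.stack(dps) if dps else np.empty((0, len(samples)), dtype=np.int32)
    matrix = GenotypeMatrix(records, animals, genotypes, depths)
    return records, matrix


def write_vcf(path, matrix: GenotypeMatrix, contigs: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix back to VCF 4.2 (one bi-allelic record per variant)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    contigs = contigs or {}
    seen = dict(contigs)
    for v in matrix.variants:
        seen.setdefault(v.chromosome, None)
    for name, length in seen.items():
        if length:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    for animal_id, _ in matrix.animals:
        header.add_sample(animal_id)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(matrix.variants):
            rec = out.new_record(
                contig=v.chromosome,
                start=v.position - 1,
                stop=v.position - 1 + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele),
                id=None if v.id == "." else v.id,
            )
            for j, (animal_id, _) in enumerate(matrix.animals):
                a, b = matrix.genotypes[i, j]
                rec.samples[animal_id]["GT"] = (
                    None if a < 0 else int(a),
                    None if b < 0 else int(b),
                )
                if matrix.depths[i, j] >= 0:
                    rec.samples[animal_id]["DP"] = int(matrix.depths[i, j])
            out.write(rec)


def read_groups(path) -> dict[str, str]:
    """Read a 2-column TSV (animal_id, group) into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            animal, group = line.split("\t")[:2]
            if animal.lower() in {"animal_id", "animal", "id"}:
                continue
            out[animal] = group
    return out


# -- filtering and normalization ------------------------------------------


def filter_by_depth(matrix: GenotypeMatrix, min_depth: int = MIN_DEPTH_DEFAULT) -> GenotypeMatrix:
    """Set calls with known depth below ``min_depth`` to missing.

    Calls with unknown depth are kept.  ``min_depth=0`` is the identity.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    genotypes = matrix.genotypes.copy()
    low = (matrix.depths >= 0) & (matrix.depths < min_depth)
    genotypes[low] = -1
    return GenotypeMatrix(
        list(matrix.variants), list(matrix.animals), genotypes, matrix.depths.copy()
    )


def normalize(record: VariantRecord) -> VariantRecord:
    """Trim shared flanking bases (trailing first, then leading, keeping an
    anchor base for InDels)."""
    ref, alt, pos = record.ref_allele, record.alt_allele, record.position
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(record, position=pos, ref_allele=ref, alt_allele=alt)


def _align_alleles(ref: str, alt: str):
    """Global alignment of alt against ref (match +1, mismatch -1, gap -2)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(ref, alt)[0]
    return aln[0], aln[1]  # gapped ref, gapped alt


def decompose_mnp(record: VariantRecord) -> list[VariantRecord]:
    """Decompose an MNP/complex record into atomic SNPs and InDels.

    Equal-length records split positionally after flank trimming; unequal
    lengths are resolved by global pairwise alignment and column
    classification.  Already-atomic records are returned unchanged.  The
    joint application of the returned records to the reference reproduces
    the alternate haplotype.
    """
    rec = normalize(record)
    ref, alt = rec.ref_allele, rec.alt_allele
    if rec.variant_class in {"SNP", "insertion", "deletion"} and (
        len(ref) == 1 or len(alt) == 1
    ):
        return [rec]

    out: list[VariantRecord] = []
    if len(ref) == len(alt):
        for i, (r, a) in enumerate(zip(ref, alt)):
            if r != a:
                out.append(
                    VariantRecord(rec.chromosome, rec.position + i, r, a, rec.id)
                )
        return out

    gapped_ref, gapped_alt = _align_alleles(ref, alt)
    n = len(gapped_ref)
    consumed = 0  # ref bases consumed so far
    i = 0
    while i < n:
        r, a = gapped_ref[i], gapped_alt[i]
        if r != "-" and a != "-":
            consumed += 1
            if r != a:
                out.append(
                    VariantRecord(
                        rec.chromosome, rec.position + consumed - 1, r, a, rec.id
                    )
                )
            i += 1
        elif r == "-":  # insertion run
            j = i
            while j < n and gapped_ref[j] == "-":
                j += 1
            ins = gapped_alt[i:j]
            if consumed == 0:
                # insertion before the first ref base: fold the next aligned
                # column in so the anchor base is not represented twice
                r2, a2 = gapped_ref[j], gapped_alt[j]
                out.append(
                    VariantRecord(rec.chromosome, rec.position, r2, ins + a2, rec.id)
                )
                consumed += 1
                i = j + 1
                continue
            else:
                anchor_pos = rec.position + consumed - 1
                if out and out[-1].position == anchor_pos:
                    # the anchor base was itself substituted: merge into one
                    # atomic insertion-with-substitution record
                    prev = out.pop()
                    out.append(
                        VariantRecord(
                            rec.chromosome, anchor_pos, prev.ref_allele,
                            prev.alt_allele + ins, rec.id,
                        )
                    )
                else:
                    anchor = ref[consumed - 1]
                    out.append(
                        VariantRecord(
                            rec.chromosome, anchor_pos, anchor, anchor + ins, rec.id
                        )
                    )
            i = j
        else:  # deletion run
            j = i
            while j < n and gapped_alt[j] == "-":
                j += 1
            deleted = gapped_ref[i:j]
            if consumed == 0:
                # deletion of the leading bases: fold the next aligned column
                # in so the anchor base is not represented twice
                r2, a2 = gapped_ref[j], gapped_alt[j]
                out.append(
                    VariantRecord(
                        rec.chromosome, rec.position, deleted + r2, a2, rec.id
                    )
                )
                consumed += len(deleted) + 1
                i = j + 1
                continue
            else:
                anchor_pos = rec.position + consumed - 1
                if out and out[-1].position == anchor_pos:
                    prev = out.pop()
                    out.append(
                        VariantRecord(
                            rec.chromosome, anchor_pos,
                            prev.ref_allele + deleted, prev.alt_allele, rec.id,
                        )
                    )
                else:
                    anchor = ref[consumed - 1]
                    out.append(
                        VariantRecord(
                            rec.chromosome, anchor_pos, anchor + deleted, anchor, rec.id
                        )
                    )
            consumed += len(deleted)
            i = j
    return out


def apply_variants(reference: str, start: int, variants: list[VariantRecord]) -> str:
    """Apply non-overlapping variants to ``reference`` (genomic start ``start``).

    Used by tests and truth-table checks to verify decomposition: the
    variants' joint application must rebuild the alternate haplotype.
    """
    edits = sorted(variants, key=lambda v: v.position, reverse=True)
    seq = reference
    for v in edits:
        i = v.position - start
        assert seq[i : i + len(v.ref_allele)] == v.ref_allele, "ref mismatch"
        seq = seq[:i] + v.alt_allele + seq[i + len(v.ref_allele) :]
    return seq


# -- allele frequencies ----------------------------------------------------


def round_half_away(x: float, digits: int = 2) -> float:
    """Round half away from zero (display convention for frequency tables)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def allele_frequency(
    matrix: GenotypeMatrix, variant: int | VariantRecord, group: str | None = "ALL"
):
    """Alternate allele frequency in a group.

    Returns ``(frequency, display)`` where display is the 2-dp
    half-away-from-zero rounded value as printed in frequency tables, or
    ``(None, None)`` when the group has no non-missing calls.
    """
    if isinstance(variant, VariantRecord):
        i = matrix.variants.index(variant)
    else:
        i = variant
    cols = matrix.group_indices(group)
    g = matrix.genotypes[i][cols]  # (n, 2)
    known = g >= 0
    n_alleles = int(known.sum())
    if n_alleles == 0:
        return None, None
    freq = float(g[known].sum()) / n_alleles
    return freq, round_half_away(freq, 2)


# -- region classification -------------------------------------------------

REGION_TAGS = ("5_upstream", "5utr", "coding", "intron", "splice_region", "3utr", "3_downstream")


def classify_region(
    record: VariantRecord,
    model: TranscriptModel,
    intronic_window: int = 8,
    exonic_window: int = 3,
) -> str:
    """Classify a variant relative to a transcript.

    One tag per (variant, transcript): coding positions are ``coding``;
    intronic positions within ``intronic_window`` bases of a junction and
    exonic positions within ``exonic_window`` bases become ``splice_region``
    (VEP-style); remaining tags follow transcription direction.
    """
    if record.chromosome != model.chromosome:
        raise ValueError("variant and transcript on different chromosomes")
    pos = record.position
    if _near_junction(model, pos, intronic_window, exonic_window):
        in_exon = any(s <= pos <= e for s, e in model.exons)
        tag = genomic_to_cds(model, pos)
        # coding positions near a junction stay coding unless intronic
        if not in_exon:
            return "splice_region"
        if not isinstance(tag, int):
            return "splice_region"
    tag = genomic_to_cds(model, pos)
    if isinstance(tag, int):
        return "coding"
    return {"upstream": "5_upstream", "downstream": "3_downstream"}.get(tag, tag)


def _near_junction(model, pos, intronic_window, exonic_window) -> bool:
    lo, hi = model.span
    if not lo <= pos <= hi:
        return False
    boundaries = []
    sorted_exons = sorted(model.exons)
    for i, (s, e) in enumerate(sorted_exons):
        if i > 0:
            boundaries.append(("acceptor_side", s))  # intron is to the left
        if i < len(sorted_exons) - 1:
            boundaries.append(("donor_side", e))  # intron is to the right
    in_exon = any(s <= pos <= e for s, e in model.exons)
    for kind, b in boundaries:
        if kind == "donor_side":
            if in_exon and b - exonic_window + 1 <= pos <= b:
                return True
            if not in_exon and b + 1 <= pos <= b + intronic_window:
                return True
        else:
            if in_exon and b <= pos <= b + exonic_window - 1:
                return True
            if not in_exon and b - intronic_window <= pos <= b - 1:
                return True
    return False
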