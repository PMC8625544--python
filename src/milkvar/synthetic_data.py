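"""Synthetic references, catalogs and cohorts with full truth tables.

The generator emulates a multi-breed diploid cattle cohort genotyped at
multi-exon milk protein genes: six genes mirroring the real loci (CSN1S1,
CSN2, CSN1S2, CSN3, LALBA, LGB; CSN2 on the reverse strand; exon counts
19/9/18/5/4/7), planted missense/synonymous/frameshift/UTR variants with
known consequences, genotypes drawn from specified casein haplotype
frequencies, and per-call depths that exercise the minimum-coverage filter.
Everything is deterministic for a fixed seed, and every planted feature is
recorded in truth tables so each pipeline stage can be verified without
any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_models import TranscriptModel
from .variant_io import GenotypeMatrix, VariantRecord, write_vcf

__all__ = [
    "GeneSpec",
    "SimConfig",
    "SyntheticReference",
    "SyntheticCohort",
    "generate_reference",
    "generate_cohort",
    "simulate_casein_cohort",
    "synthetic_lgb_model",
    "CASEIN_GENES",
    "CASEIN_ALLELE_BITS",
    "TABLE_TOTAL_HAPLOTYPE_FREQS",
    "GROUP_HAPLOTYPE_FREQS",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

_CODON_TABLE = {}  # filled lazily from Bio


def _aa_of(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for a in _BASES:
            for b in _BASES:
                for c in _BASES:
                    _CODON_TABLE[a + b + c] = str(Seq(a + b + c).translate())
    return _CODON_TABLE[codon]


def _seq3(aa: str) -> str:
    from Bio.SeqUtils import seq3

    return "*" if aa == "*" else seq3(aa)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# -- study-level constants -------------------------------------------------

CASEIN_GENES = ["CSN1S1", "CSN2", "CSN1S2", "CSN3"]

#: per casein gene: (allele encoded by 0, allele encoded by 1) in the
#: compact haplotype vectors used for simulation and EM labelling
CASEIN_ALLELE_BITS = {
    "CSN1S1": ("B", "C"),
    "CSN2": ("A1", "A2"),
    "CSN1S2": ("A", "B"),
    "CSN3": ("B", "A"),
}

#: pooled frequencies of the four major CSN1S1-CSN2-CSN1S2-CSN3 haplotypes
TABLE_TOTAL_HAPLOTYPE_FREQS = {
    "B-A1-A-B": 0.39,
    "B-A2-A-B": 0.22,
    "B-A1-A-A": 0.20,
    "C-A2-A-A": 0.19,
}

#: per-breed casein haplotype frequencies (haplotypes below 1% dropped;
#: renormalized at sampling time)
GROUP_HAPLOTYPE_FREQS = {
    "Crossbreed": {"B-A1-A-B": 0.01, "B-A2-A-B": 0.20, "B-A1-A-A": 0.39, "C-A2-A-B": 0.38},
    "Lagune": {"B-A1-A-B": 0.50, "B-A2-A-B": 0.18, "B-A1-A-A": 0.29},
    "Somba": {
        "B-A1-A-B": 0.47,
        "B-A2-A-B": 0.25,
        "B-A1-A-A": 0.20,
        "C-A2-A-A": 0.02,
        "C-A2-A-B": 0.02,
    },
}

#: pooled allele frequencies for the two whey protein genes
GENE_ALLELE_FREQS = {
    "LALBA": {"B": 0.82, "A": 0.05, "E": 0.07, "F": 0.06},
    "LGB": {"B": 0.78, "B1": 0.20, "K": 0.02},
}


def haplotype_label(bits: tuple[int, ...]) -> str:
    return "-".join(
        CASEIN_ALLELE_BITS[g][b] for g, b in zip(CASEIN_GENES, bits)
    )


def haplotype_bits(label: str) -> tuple[int, ...]:
    parts = label.split("-")
    return tuple(
        CASEIN_ALLELE_BITS[g].index(a) for g, a in zip(CASEIN_GENES, parts)
    )


@dataclass(frozen=True)
class GeneSpec:
    name: str
    chromosome: str
    exon_count: int
    precursor_length: int  # residues, stop codon excluded
    strand: str
    precursor_offset: int


#: synthetic counterparts of the six milk protein genes.  Exon counts and
#: strands mirror the real loci; the CSN2 precursor is lengthened to 260
#: residues so that the nomenclature-table offset of 50 can host the
#: CSN2 L variant at precursor position 247.
DEFAULT_GENES = [
    GeneSpec("CSN1S1", "6", 19, 214, "+", 15),
    GeneSpec("CSN2", "6", 9, 260, "-", 50),
    GeneSpec("CSN1S2", "6", 18, 222, "+", 15),
    GeneSpec("CSN3", "6", 5, 190, "+", 21),
    GeneSpec("LALBA", "5", 4, 142, "+", 48),
    GeneSpec("LGB", "11", 7, 178, "+", 16),
]


@dataclass
class SimConfig:
    seed: int = 0
    genes: list[GeneSpec] = field(default_factory=lambda: list(DEFAULT_GENES))
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("Crossbreed", 27), ("Lagune", 20), ("Somba", 20)]
    )
    group_haplotype_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in GROUP_HAPLOTYPE_FREQS.items()}
    )
    gene_allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in GENE_ALLELE_FREQS.items()}
    )
    #: rare alleles layered onto a base casein haplotype allele:
    #: gene -> (base allele, rare allele, probability per chromosome)
    rare_overlays: dict[str, tuple[str, str, float]] = field(
        default_factory=lambda: {
            "CSN2": ("A1", "L", 0.01),
            "CSN3": ("B", "K", 0.015),
            "CSN1S2": ("A", "B", 0.01),
        }
    )
    #: alt-allele frequency for non-catalog planted variants (synonymous,
    #: signal-peptide, UTR/regulatory)
    background_alt_freq: float = 0.08
    depth_range: tuple[int, int] = (2, 60)
    utr5_length: int = 60
    utr3_length: int = 150
    intron_length: int = 120


# -- planted features ------------------------------------------------------


@dataclass(frozen=True)
class _CodingPlant:
    gene: str
    precursor_residue: int
    ref_codon: str
    alt_codon: str | None  # None => frameshift insertion (handled specially)
    allele_name: str | None
    kind: str  # missense | synonymous | frameshift


_CODING_PLANTS = [
    _CodingPlant("CSN1S1", 207, "GAA", "GGA", "C", "missense"),
    _CodingPlant("CSN2", 117, "CAC", "CCC", "A2", "missense"),
    _CodingPlant("CSN2", 247, "GTA", "GCA", "L", "missense"),
    _CodingPlant("CSN2", 42, "GCT", "GCC", None, "synonymous"),
    _CodingPlant("CSN1S2", 23, "TCT", "TTT", "B", "missense"),
    _CodingPlant("CSN3", 87, "GCC", "GTC", "K", "missense"),
    _CodingPlant("CSN3", 157, "ATA", "ACA", "A", "missense"),
    _CodingPlant("CSN3", 169, "GCT", "GAT", "A", "missense"),
    _CodingPlant("LALBA", 58, "CGG", "TGG", "F", "missense"),
    _CodingPlant("LALBA", 58, "CGG", "CAG", "A", "missense"),
    _CodingPlant("LALBA", 89, "ATA", "GTA", "E", "missense"),
    _CodingPlant("LALBA", 112, "GAC", "GAT", None, "synonymous"),
    _CodingPlant("LGB", 18, "ATT", "ATC", None, "synonymous"),
    _CodingPlant("LGB", 104, "AAT", "AAC", None, "synonymous"),
    _CodingPlant("LGB", 113, "ACC", "ACT", None, "synonymous"),
    _CodingPlant("LGB", 134, "GCC", "GTC", "B1", "missense"),
    _CodingPlant("LGB", 108, "ACA", None, "K", "frameshift"),
]

#: codons that must be fixed so the LGB frameshift reproduces the published
#: arithmetic: Thr at precursor 108, 13 changed residues in the new frame,
#: then a stop (see tests for the hand-derivation)
_LGB_FRAME_BLOCK = {
    107: "CTG",
    108: "ACA",
    **{i: "GCT" for i in range(109, 121)},
    113: "ACC",  # hosts the Thr97 synonymous site; shifted frame stays stop-free
    121: "AAG",
}

# seeds are synthetic; the names echo miRNAs reported at these genes
_DEFAULT_SEEDS = [
    ("bta-miR-2464-3p", "AGUCGUA"),
    ("bta-miR-452", "AACUGUU"),
    ("bta-miR-2291", "CCAGAGU"),
]

# sharp 6-column motifs: a single core mismatch falls below the 0.85
# relative-score threshold
_DEFAULT_PWMS = [("STAT5A", "TTCCAG"), ("STAT1", "GGTACA")]
_PWM_MAJOR = 0.91
_PWM_MINOR = 0.03


@dataclass(frozen=True)
class _UTRPlant:
    gene: str
    region: str  # 5utr | 3utr
    kind: str  # mirna | tfbs
    element: str  # seed or TF name
    effect: str  # loss | gain
    offset: int  # position of the planted block within the UTR (0-based)


_UTR_PLANTS = [
    _UTRPlant("CSN2", "3utr", "mirna", "bta-miR-2464-3p", "loss", 40),
    _UTRPlant("CSN1S2", "5utr", "mirna", "bta-miR-452", "gain", 20),
    _UTRPlant("CSN1S1", "5utr", "tfbs", "STAT5A", "loss", 22),
    _UTRPlant("LGB", "5utr", "tfbs", "STAT1", "gain", 24),
]


def _seed_core6(seed_rna: str) -> str:
    return _revcomp(seed_rna[:6].replace("U", "T"))


def _seed_m8_target(seed_rna: str) -> str:
    return seed_rna[6].replace("U", "T").translate(str.maketrans("ACGT", "TGCA"))


def _forbidden_strings() -> list[str]:
    out = []
    for _, seed in _DEFAULT_SEEDS:
        out.append(_seed_core6(seed))
    for _, consensus in _DEFAULT_PWMS:
        out.append(consensus)
        out.append(_revcomp(consensus))
    return out


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _scrub(seq: str, rng) -> str:
    """Resample bases until no forbidden motif string occurs in the sequence."""
    forbidden = _forbidden_strings()
    seq = list(seq)
    for _ in range(100):
        text = "".join(seq)
        dirty = False
        for f in forbidden:
            i = text.find(f)
            while i >= 0:
                dirty = True
                j = i + len(f) // 2
                choices = [b for b in _BASES if b != seq[j]]
                seq[j] = rng.choice(choices)
                text = "".join(seq)
                i = text.find(f)
        if not dirty:
            return text
    raise RuntimeError("could not scrub forbidden motifs")


# -- reference generation --------------------------------------------------


@dataclass
class PlantedVariant:
    """Truth record for one planted variant (plus-strand VCF representation)."""

    gene: str
    chromosome: str
    position: int
    ref: str
    alt: str
    region: str  # coding | 5utr | 3utr
    kind: str  # missense | synonymous | frameshift | utr_snp
    allele_name: str | None = None
    precursor_notation: str | None = None
    mature_notation: str | None = None
    mirna_loss: list = field(default_factory=list)
    mirna_gain: list = field(default_factory=list)
    tfbs_loss: list = field(default_factory=list)
    tfbs_gain: list = field(default_factory=list)
    vcf_id: str = "."


@dataclass
class SyntheticReference:
    config: SimConfig
    fasta_path: Path
    gff3_path: Path
    catalog_path: Path
    seeds_path: Path
    pwms_path: Path
    truth_path: Path
    planted: list[PlantedVariant]
    offsets: dict[str, int]
    transcript_ids: dict[str, str]


def _build_cds(rng, spec: GeneSpec, plants: list[_CodingPlant]) -> str:
    """Coding-orientation CDS (incl. stop) with planted codons fixed."""
    n = spec.precursor_length
    fixed: dict[int, str] = {}
    if spec.name == "LGB":
        fixed.update(_LGB_FRAME_BLOCK)
    for p in plants:
        if p.ref_codon is not None:
            prev = fixed.get(p.precursor_residue)
            if prev is not None and prev != p.ref_codon:
                raise ValueError(f"conflicting planted codons at {spec.name}:{p.precursor_residue}")
            fixed[p.precursor_residue] = p.ref_codon
    codons = ["ATG"]
    for i in range(2, n + 1):
        codons.append(fixed.get(i) or str(rng.choice(_SAFE_CODONS)))
    codons.append("TAA")
    return "".join(codons)


class _GeneLayout:
    """Coding-orientation layout of one gene, mapped to plus-strand coords."""

    def __init__(self, rng, spec: GeneSpec, cds: str, config: SimConfig):
        self.spec = spec
        self.cds = cds
        utr5 = _scrub(_random_seq(rng, config.utr5_length), rng)
        utr3 = _scrub(_random_seq(rng, config.utr3_length), rng)
        self.utr5 = list(utr5)
        self.utr3 = list(utr3)
        n_pieces = spec.exon_count
        base, extra = divmod(len(cds), n_pieces)
        sizes = [base + (1 if i < extra else 0) for i in range(n_pieces)]
        self.cds_pieces = []
        at = 0
        for s in sizes:
            self.cds_pieces.append(cds[at : at + s])
            at += s
        self.introns = [
            "GT" + _random_seq(rng, config.intron_length - 4) + "AG"
            for _ in range(n_pieces - 1)
        ]

    # coding-orientation index arithmetic -------------------------------

    def coding_sequence_parts(self):
        """Ordered (kind, text) parts in coding orientation."""
        parts = [("utr5", "".join(self.utr5))]
        for i, piece in enumerate(self.cds_pieces):
            parts.append((f"cds{i}", piece))
            if i < len(self.introns):
                parts.append((f"intron{i}", self.introns[i]))
        parts.append(("utr3", "".join(self.utr3)))
        return parts

    def coding_index_of_cds(self, cds_pos: int) -> int:
        """0-based index in the assembled coding-orientation gene of CDS pos."""
        at = len(self.utr5)
        remaining = cds_pos - 1
        for i, piece in enumerate(self.cds_pieces):
            if remaining < len(piece):
                return at + remaining
            at += len(piece)
            remaining -= len(piece)
            if i < len(self.introns):
                at += len(self.introns[i])
        raise ValueError("CDS position out of range")

    def coding_index_of_utr(self, region: str, offset: int) -> int:
        if region == "5utr":
            return offset
        total = sum(len(t) for _, t in self.coding_sequence_parts())
        return total - len(self.utr3) + offset


def generate_reference(config: SimConfig, out_dir) -> SyntheticReference:
    """Write FASTA + GFF3 + catalog + seed/PWM files + truth JSON.

    Deterministic for a fixed ``config.seed``; every gene has a valid ORF
    and every planted feature is recorded with its coordinates and expected
    annotation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    plants_by_gene: dict[str, list[_CodingPlant]] = {}
    for p in _CODING_PLANTS:
        plants_by_gene.setdefault(p.gene, []).append(p)
    utr_by_gene: dict[str, list[_UTRPlant]] = {}
    for u in _UTR_PLANTS:
        utr_by_gene.setdefault(u.gene, []).append(u)
    seeds = dict(_DEFAULT_SEEDS)
    pwm_consensus = dict(_DEFAULT_PWMS)

    chrom_seqs: dict[str, list[str]] = {}
    chrom_len: dict[str, int] = {}
    gff_lines = ["##gff-version 3"]
    planted: list[PlantedVariant] = []
    catalog_rows: list[tuple] = []
    offsets: dict[str, int] = {}
    transcript_ids: dict[str, str] = {}
    gene_coords: dict[str, dict] = {}

    for spec in config.genes:
        gene_plants = [p for p in plants_by_gene.get(spec.name, []) if p.precursor_residue <= spec.precursor_length]
        cds = _build_cds(rng, spec, gene_plants)
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length of {spec.name} not a multiple of 3")
        layout = _GeneLayout(rng, spec, cds, config)
        gene_variants, gene_catalog = _plant_variants(
            layout, gene_plants, utr_by_gene.get(spec.name, []), seeds, pwm_consensus, spec
        )

        coding_seq = "".join(t for _, t in layout.coding_sequence_parts())
        start = chrom_len.get(spec.chromosome, 0) + 2200  # pad between genes
        plus_seq = coding_seq if spec.strand == "+" else _revcomp(coding_seq)
        gene_start = start + 1  # 1-based genomic start
        gene_end = gene_start + len(plus_seq) - 1

        # genomic position of coding-orientation index i
        def genomic_of(i: int) -> int:
            if spec.strand == "+":
                return gene_start + i
            return gene_end - i

        # exon/CDS intervals in coding orientation -> genomic
        exon_ivals, cds_ivals = _intervals(layout, genomic_of, spec.strand)
        tid = f"{spec.name}-t1"
        transcript_ids[spec.name] = tid
        offsets[spec.name] = spec.precursor_offset
        gff_lines.append(
            f"{spec.chromosome}\tmilkvar\tgene\t{min(gene_start, gene_end)}\t{gene_end}\t.\t{spec.strand}\t.\tID=gene-{spec.name};Name={spec.name}"
        )
        gff_lines.append(
            f"{spec.chromosome}\tmilkvar\tmRNA\t{gene_start}\t{gene_end}\t.\t{spec.strand}\t.\tID={tid};Parent=gene-{spec.name}"
        )
        for k, (s, e) in enumerate(sorted(exon_ivals), start=1):
            gff_lines.append(
                f"{spec.chromosome}\tmilkvar\texon\t{s}\t{e}\t.\t{spec.strand}\t.\tID={tid}-exon{k};Parent={tid}"
            )
        for k, (s, e) in enumerate(sorted(cds_ivals), start=1):
            gff_lines.append(
                f"{spec.chromosome}\tmilkvar\tCDS\t{s}\t{e}\t.\t{spec.strand}\t0\tID={tid}-cds{k};Parent={tid}"
            )

        pad = _random_seq(rng, 2200)
        chrom_seqs.setdefault(spec.chromosome, []).append(pad + plus_seq)
        chrom_len[spec.chromosome] = chrom_len.get(spec.chromosome, 0) + 2200 + len(plus_seq)
        gene_coords[spec.name] = {
            "chromosome": spec.chromosome,
            "start": gene_start,
            "end": gene_end,
            "strand": spec.strand,
            "transcript_id": tid,
            "precursor_length": spec.precursor_length,
        }

        # translate coding-orientation variant placements to plus strand
        for v in gene_variants:
            planted.append(_to_plus_strand(v, layout, genomic_of, spec))
        for row in gene_catalog:
            catalog_rows.append(row)

    # resolve catalog rows: coding-orientation placements -> final records
    catalog_final = _finalize_catalog(catalog_rows, planted)

    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        for chrom, chunks in chrom_seqs.items():
            fh.write(f">{chrom}\n")
            seq = "".join(chunks)
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    gff3_path = out_dir / "genes.gff3"
    gff3_path.write_text("\n".join(gff_lines) + "\n")

    catalog_path = out_dir / "allele_catalog.tsv"
    with open(catalog_path, "w") as fh:
        fh.write("#gene\tallele_name\tchrom\tpos\tref\talt\trequired_allele\tstatus\tid\n")
        for row in catalog_final:
            fh.write("\t".join(map(str, row)) + "\n")

    seeds_path = out_dir / "mirna_seeds.tsv"
    with open(seeds_path, "w") as fh:
        fh.write("miR family\tSeed+m8\tSpecies ID\n")
        for name, seed in _DEFAULT_SEEDS:
            fh.write(f"{name}\t{seed}\t9913\n")

    pwms_path = out_dir / "tf_motifs.jaspar"
    with open(pwms_path, "w") as fh:
        for i, (name, consensus) in enumerate(_DEFAULT_PWMS, start=1):
            fh.write(f">MS{i:04d}.1\t{name}\n")
            counts = {b: [] for b in _BASES}
            for c in consensus:
                for b in _BASES:
                    counts[b].append(91 if b == c else 3)
            for b in _BASES:
                fh.write(f"{b}  [ " + " ".join(f"{x:3d}" for x in counts[b]) + " ]\n")

    truth = {
        "genes": gene_coords,
        "offsets": offsets,
        "transcript_ids": transcript_ids,
        "variants": [vars(v) for v in planted],
    }
    truth_path = out_dir / "truth_reference.json"
    truth_path.write_text(json.dumps(truth, indent=1, default=str))

    return SyntheticReference(
        config=config,
        fasta_path=fasta_path,
        gff3_path=gff3_path,
        catalog_path=catalog_path,
        seeds_path=seeds_path,
        pwms_path=pwms_path,
        truth_path=truth_path,
        planted=planted,
        offsets=offsets,
        transcript_ids=transcript_ids,
    )


@dataclass
class _CodingVariantPlacement:
    """A planted variant in coding-orientation coordinates."""

    coding_index: int  # 0-based index of the first reference base
    ref: str  # coding-orientation alleles
    alt: str
    region: str
    kind: str
    allele_name: str | None
    precursor_notation: str | None
    mature_notation: str | None
    mirna_loss: list = field(default_factory=list)
    mirna_gain: list = field(default_factory=list)
    tfbs_loss: list = field(default_factory=list)
    tfbs_gain: list = field(default_factory=list)


def _plant_variants(layout, gene_plants, utr_plants, seeds, pwm_consensus, spec):
    placements: list[_CodingVariantPlacement] = []
    catalog_rows: list[tuple] = []
    offset = spec.precursor_offset

    for p in gene_plants:
        if p.kind == "frameshift":
            # insertion of A after the first base of the planted codon
            cds_anchor = (p.precursor_residue - 1) * 3 + 1
            idx = layout.coding_index_of_cds(cds_anchor)
            anchor = layout.cds[cds_anchor - 1]
            mature = p.precursor_residue - offset
            placements.append(
                _CodingVariantPlacement(
                    coding_index=idx,
                    ref=anchor,
                    alt=anchor + "A",
                    region="coding",
                    kind="frameshift",
                    allele_name=p.allele_name,
                    precursor_notation=f"p.Thr{p.precursor_residue}Asnfs*13",
                    mature_notation=f"p.Thr{mature}Asnfs*13",
                )
            )
            if p.allele_name:
                catalog_rows.append((spec.name, p.allele_name, idx, anchor, anchor + "A"))
            continue
        diffs = [i for i in range(3) if p.ref_codon[i] != p.alt_codon[i]]
        assert len(diffs) == 1
        codon_off = diffs[0]
        cds_pos = (p.precursor_residue - 1) * 3 + codon_off + 1
        idx = layout.coding_index_of_cds(cds_pos)
        ref_b, alt_b = p.ref_codon[codon_off], p.alt_codon[codon_off]
        ref_aa, alt_aa = _aa_of(p.ref_codon), _aa_of(p.alt_codon)
        mature = p.precursor_residue - offset
        if p.kind == "synonymous":
            prec_note = f"p.{_seq3(ref_aa)}{p.precursor_residue}"
            mat_note = (
                f"p.{_seq3(ref_aa)}{mature}" if mature > 0 else "pre-mature region"
            )
        else:
            prec_note = f"p.{_seq3(ref_aa)}{p.precursor_residue}{_seq3(alt_aa)}"
            mat_note = (
                f"p.{_seq3(ref_aa)}{mature}{_seq3(alt_aa)}"
                if mature > 0
                else "pre-mature region"
            )
        placements.append(
            _CodingVariantPlacement(
                coding_index=idx,
                ref=ref_b,
                alt=alt_b,
                region="coding",
                kind=p.kind,
                allele_name=p.allele_name,
                precursor_notation=prec_note,
                mature_notation=mat_note,
            )
        )
        if p.allele_name:
            catalog_rows.append((spec.name, p.allele_name, idx, ref_b, alt_b))

    for u in utr_plants:
        placements.append(_plant_utr(layout, u, seeds, pwm_consensus))

    return placements, catalog_rows


def _plant_utr(layout, u: _UTRPlant, seeds, pwm_consensus) -> _CodingVariantPlacement:
    """Write a regulatory element block into a UTR and return its variant."""
    utr = layout.utr5 if u.region == "5utr" else layout.utr3
    if u.kind == "mirna":
        seed = seeds[u.element]
        core = _seed_core6(seed)
        block = _seed_m8_target(seed) + core + "A"  # an 8mer site
        var_in_block = 1 + 2  # third base of the core
        site_base = block[var_in_block]
        broken = [b for b in _BASES if b != site_base][0]
        if u.effect == "loss":
            ref_block, ref_b, alt_b = block, site_base, broken
        else:
            ref_block = block[:var_in_block] + broken + block[var_in_block + 1 :]
            ref_b, alt_b = broken, site_base
        entry = (u.element, "8mer")
    else:
        consensus = pwm_consensus[u.element]
        var_in_block = len(consensus) // 2
        site_base = consensus[var_in_block]
        broken = [b for b in _BASES if b != site_base][0]
        if u.effect == "loss":
            ref_block, ref_b, alt_b = consensus, site_base, broken
        else:
            ref_block = consensus[:var_in_block] + broken + consensus[var_in_block + 1 :]
            ref_b, alt_b = broken, site_base
        entry = u.element
    for i, b in enumerate(ref_block):
        utr[u.offset + i] = b
    placement = _CodingVariantPlacement(
        coding_index=layout.coding_index_of_utr(u.region, u.offset + var_in_block),
        ref=ref_b,
        alt=alt_b,
        region=u.region,
        kind="utr_snp",
        allele_name=None,
        precursor_notation=None,
        mature_notation=None,
    )
    if u.kind == "mirna" and u.effect == "loss":
        placement.mirna_loss.append(entry)
    elif u.kind == "mirna":
        placement.mirna_gain.append(entry)
    elif u.effect == "loss":
        placement.tfbs_loss.append(entry)
    else:
        placement.tfbs_gain.append(entry)
    return placement


def _intervals(layout, genomic_of, strand):
    """Exon and CDS genomic intervals from the coding-orientation layout."""
    exon_ivals = []
    cds_ivals = []
    at = 0
    parts = layout.coding_sequence_parts()
    # exons: utr5 + cds0 is exon 1; cds_i alone for middle; cds_last + utr3 last
    n_pieces = len(layout.cds_pieces)
    exon_bounds = []
    # compute coding-orientation [start, end] of each exon
    pos = 0
    for i, (kind, text) in enumerate(parts):
        if kind.startswith("cds"):
            k = int(kind[3:])
            s = pos
            e = pos + len(text) - 1
            cds_ivals.append((s, e))
            exon_s = s - (len(layout.utr5) if k == 0 else 0)
            exon_e = e + (len(layout.utr3) if k == n_pieces - 1 else 0)
            exon_bounds.append((exon_s, exon_e))
        pos += len(text)

    def to_genomic(iv):
        a, b = genomic_of(iv[0]), genomic_of(iv[1])
        return (min(a, b), max(a, b))

    exon_ivals = [to_genomic(iv) for iv in exon_bounds]
    cds_ivals = [to_genomic(iv) for iv in cds_ivals]
    return exon_ivals, cds_ivals


def _to_plus_strand(v: _CodingVariantPlacement, layout, genomic_of, spec) -> PlantedVariant:
    if spec.strand == "+" or len(v.ref) == len(v.alt) == 1:
        if spec.strand == "+":
            pos = genomic_of(v.coding_index)
            ref, alt = v.ref, v.alt
        else:
            pos = genomic_of(v.coding_index)
            ref, alt = _revcomp(v.ref), _revcomp(v.alt)
    else:
        raise NotImplementedError("planted InDels only supported on plus-strand genes")
    return PlantedVariant(
        gene=spec.name,
        chromosome=spec.chromosome,
        position=pos,
        ref=ref,
        alt=alt,
        region=v.region,
        kind=v.kind,
        allele_name=v.allele_name,
        precursor_notation=v.precursor_notation,
        mature_notation=v.mature_notation,
        mirna_loss=v.mirna_loss,
        mirna_gain=v.mirna_gain,
        tfbs_loss=v.tfbs_loss,
        tfbs_gain=v.tfbs_gain,
    )


def _finalize_catalog(catalog_rows, planted):
    """Catalog rows (gene, allele, coding idx, ref, alt) -> final TSV rows."""
    final = []
    by_key = {}
    for v in planted:
        if v.allele_name:
            by_key[(v.gene, v.allele_name, v.ref if len(v.ref) == 1 else v.ref[0])] = v
    # reference alleles: one row per gene at its first defining site
    genes_seen = {}
    for v in planted:
        if v.allele_name:
            genes_seen.setdefault(v.gene, []).append(v)
    ref_names = {
        "CSN1S1": "B",
        "CSN2": "A1",
        "CSN1S2": "A",
        "CSN3": "B",
        "LALBA": "B",
        "LGB": "B",
    }
    for gene, variants in genes_seen.items():
        variants = sorted(variants, key=lambda v: v.position)
        ref_name = ref_names.get(gene, "REF")
        first = variants[0]
        final.append(
            (gene, ref_name, first.chromosome, first.position, first.ref, first.alt, first.ref, "reference", ".")
        )
        for v in variants:
            final.append(
                (gene, v.allele_name, v.chromosome, v.position, v.ref, v.alt, v.alt, "known", ".")
            )
    return final


# -- cohort generation -----------------------------------------------------


@dataclass
class SyntheticCohort:
    reference: SyntheticReference
    matrix: GenotypeMatrix
    vcf_path: Path
    groups_path: Path
    truth_path: Path
    #: animal id -> {gene: (allele, allele)} true allele pairs
    true_alleles: dict[str, dict[str, tuple[str, str]]]
    #: animal id -> (casein haplotype label, casein haplotype label)
    true_haplotypes: dict[str, tuple[str, str]]


def _renormalize(freqs: dict[str, float]) -> tuple[list[str], np.ndarray]:
    labels = list(freqs)
    p = np.array([freqs[k] for k in labels], dtype=float)
    return labels, p / p.sum()


def generate_cohort(reference: SyntheticReference, out_dir) -> SyntheticCohort:
    """Draw a diploid cohort from the configured haplotype/allele frequencies.

    Two casein haplotypes per animal come from the group-specific casein
    frequencies (rare alleles overlaid at their configured rates); LALBA
    and LGB allele pairs from per-gene frequencies; other planted variants
    segregate independently at the background frequency.  Depths are
    uniform integers over ``config.depth_range``.
    """
    config = reference.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1_000_003)

    from .allele_typing import load_catalog

    catalog = load_catalog(reference.catalog_path)

    animals: list[tuple[str, str]] = []
    for group, n in config.groups:
        for i in range(n):
            animals.append((f"{group[:3].upper()}{i+1:03d}", group))

    # per-animal haplotype-level allele names for every gene
    true_alleles: dict[str, dict[str, tuple[str, str]]] = {}
    true_haps: dict[str, tuple[str, str]] = {}
    per_animal_gene_haps: dict[str, dict[str, list[str]]] = {}
    for animal_id, group in animals:
        labels, p = _renormalize(config.group_haplotype_freqs[group])
        draw = [labels[rng.choice(len(labels), p=p)] for _ in range(2)]
        gene_haps: dict[str, list[str]] = {}
        final_draw = []
        for label in draw:
            alleles = dict(zip(CASEIN_GENES, label.split("-")))
            for gene, (base, rare, prob) in config.rare_overlays.items():
                if alleles.get(gene) == base and rng.random() < prob:
                    alleles[gene] = rare
            final_draw.append("-".join(alleles[g] for g in CASEIN_GENES))
            for gene in CASEIN_GENES:
                gene_haps.setdefault(gene, []).append(alleles[gene])
        for gene, freqs in config.gene_allele_freqs.items():
            labels_g, p_g = _renormalize(freqs)
            gene_haps[gene] = [
                labels_g[rng.choice(len(labels_g), p=p_g)] for _ in range(2)
            ]
        true_haps[animal_id] = tuple(sorted(final_draw))
        per_animal_gene_haps[animal_id] = gene_haps
        true_alleles[animal_id] = {
            g: tuple(sorted(h)) for g, h in gene_haps.items()
        }

    # genotypes at every planted variant
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    allele_sites = {}  # (gene, allele) -> set of variant list indices
    planted_sorted = sorted(
        reference.planted, key=lambda v: (v.chromosome, v.position, v.alt)
    )
    for v in planted_sorted:
        records.append(
            VariantRecord(v.chromosome, v.position, v.ref, v.alt, v.vcf_id)
        )
    # map catalog requirements: for each gene allele, which variant indices
    # must carry alt
    var_index = {
        (r.chromosome, r.position, r.alt_allele): i for i, r in enumerate(records)
    }
    requires_alt: dict[tuple[str, str], set[int]] = {}
    for gene, defs in catalog.definitions.items():
        for name, definition in defs.items():
            idxs = set()
            for (chrom, pos), allele in definition.defining_sites.items():
                ref, alt = catalog.sites[gene][(chrom, pos)]
                if allele == alt:
                    idxs.add(var_index[(chrom, pos, alt)])
            requires_alt[(gene, name)] = idxs

    catalog_var_idx = set().union(*requires_alt.values()) if requires_alt else set()

    n_var, n_ani = len(records), len(animals)
    genotypes = np.zeros((n_var, n_ani, 2), dtype=np.int8)
    for j, (animal_id, _) in enumerate(animals):
        gene_haps = per_animal_gene_haps[animal_id]
        for gene, haps in gene_haps.items():
            if gene not in catalog.definitions:
                continue
            for c, name in enumerate(haps):
                for vi in requires_alt.get((gene, name), ()):  # alt-defining sites
                    genotypes[vi, j, c] = 1
    # background variants segregate independently
    for vi, v in enumerate(planted_sorted):
        if vi in catalog_var_idx:
            continue
        draws = rng.random((n_ani, 2)) < config.background_alt_freq
        genotypes[vi][draws] = 1
    # guarantee a carrier of every background variant (catalog sites may
    # legitimately be monomorphic in a small cohort)
    for vi in range(n_var):
        if vi in catalog_var_idx:
            continue
        if genotypes[vi].sum() == 0:
            j = int(rng.integers(n_ani))
            genotypes[vi, j, 1] = 1

    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, size=(n_var, n_ani)).astype(np.int32)
    matrix = GenotypeMatrix(records, animals, genotypes, depths)

    vcf_path = out_dir / "cohort.vcf"
    write_vcf(vcf_path, matrix)
    groups_path = out_dir / "groups.tsv"
    with open(groups_path, "w") as fh:
        fh.write("animal_id\tgroup\n")
        for animal_id, group in animals:
            fh.write(f"{animal_id}\t{group}\n")

    truth = {
        "true_haplotypes": {k: list(v) for k, v in true_haps.items()},
        "true_alleles": {
            k: {g: list(p) for g, p in d.items()} for k, d in true_alleles.items()
        },
    }
    truth_path = out_dir / "truth_cohort.json"
    truth_path.write_text(json.dumps(truth, indent=1))

    return SyntheticCohort(
        reference=reference,
        matrix=matrix,
        vcf_path=vcf_path,
        groups_path=groups_path,
        truth_path=truth_path,
        true_alleles=true_alleles,
        true_haplotypes=true_haps,
    )


# -- compact casein simulation for EM experiments -------------------------


def simulate_casein_cohort(
    haplotype_freqs: dict[str, float], n: int, seed: int
) -> GenotypeMatrix:
    """Unphased diploid genotypes at the four casein loci.

    Each animal receives two haplotypes drawn from ``haplotype_freqs``
    (renormalized); phase is discarded.  The four loci are represented as
    dummy bi-allelic variants in cluster order, so the result feeds
    directly into the EM estimator.
    """
    rng = np.random.default_rng(seed)
    labels, p = _renormalize(haplotype_freqs)
    vectors = np.array([haplotype_bits(l) for l in labels], dtype=np.int8)
    draws = rng.choice(len(labels), size=(n, 2), p=p)
    genotypes = np.zeros((4, n, 2), dtype=np.int8)
    for j in range(n):
        genotypes[:, j, 0] = vectors[draws[j, 0]]
        genotypes[:, j, 1] = vectors[draws[j, 1]]
    records = [
        VariantRecord("6", 1000 + 100 * i, "A", "C", f"locus{i+1}") for i in range(4)
    ]
    animals = [(f"IND{j+1:04d}", "ALL") for j in range(n)]
    depths = np.full((4, n), 30, dtype=np.int32)
    return GenotypeMatrix(records, animals, genotypes, depths)


# -- the beta-lactoglobulin demonstration model ----------------------------


def synthetic_lgb_model(seed: int = 7) -> TranscriptModel:
    """Synthetic stand-in for the bovine beta-lactoglobulin (LGB) transcript.

    This is NOT the Ensembl sequence: it is a generated 178-codon precursor
    whose geometry reproduces the published frameshift arithmetic — a
    7-exon gene on chromosome 11 (plus strand) where inserting an adenine
    after position 11:103257980 in exon 3 changes Thr at precursor residue
    108 (mature 92, offset 16) to Asn and brings a premature stop after 13
    changed residues, truncating the product at mature residue 104.
    """
    rng = np.random.default_rng(seed)
    fixed = dict(_LGB_FRAME_BLOCK)
    # codons hosting the other published LGB sites (Ile2, Asn88, Ala118)
    fixed.update({18: "ATT", 104: "AAT", 134: "GCC"})
    codons = ["ATG"]
    for i in range(2, 179):
        codons.append(fixed.get(i) or str(rng.choice(_SAFE_CODONS)))
    codons.append("TAA")
    cds = "".join(codons)  # 537 nt
    assert cds[321] == "A" and cds[322] == "C"  # codon 108 = ACA

    piece_sizes = [60, 90, 180, 120, 87]
    assert sum(piece_sizes) == len(cds)
    cds_starts = [103255940, 103256800, 103257809, 103259162, 103259600]
    cds_ivals = [(s, s + n - 1) for s, n in zip(cds_starts, piece_sizes)]
    # anchor check: CDS position 322 sits at 11:103257980 in exon 3
    assert cds_ivals[2][0] + (322 - (60 + 90) - 1) == 103257980
    exons = [
        (103255800, 103255999),  # 5'UTR + CDS piece 1
        cds_ivals[1],
        cds_ivals[2],
        cds_ivals[3],
        (103259600, 103259766),  # CDS piece 5 + start of 3'UTR
        (103260700, 103260900),  # 3'UTR
        (103264500, 103264876),  # 3'UTR
    ]
    region_start = 103253800
    region_end = 103266876
    region = list(_random_seq(rng, region_end - region_start + 1))
    at = 0
    for (s, _e), n in zip(cds_ivals, piece_sizes):
        region[s - region_start : s - region_start + n] = cds[at : at + n]
        at += n
    return TranscriptModel(
        gene_name="LGB",
        transcript_id="LGB-synthetic-t1",
        chromosome="11",
        strand="+",
        exons=exons,
        cds_intervals=cds_ivals,
        cds_sequence=cds,
        precursor_offset=16,
        region_start=region_start,
        region_sequence="".join(region),
    )
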