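"""miRNA seed-match and PWM-based TFBS gain/loss scanning of UTR variants.

A variant in untranslated or flanking sequence can create or destroy a
miRNA seed-match site (6mer/7mer-A1/7mer-m8/8mer classes) or shift a
transcription-factor binding site across a position-weight-matrix score
threshold.  Reference and alternate sequence windows around the variant are
scanned and the differences reported as losses (sites present only with
the reference allele) and gains (only with the alternate).

Only site presence and class are scored; context scoring (local AU
content, conservation) is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gene_models import TranscriptModel
from .variant_io import VariantRecord, classify_region

__all__ = [
    "SeedRecord",
    "PWM",
    "GainLossReport",
    "read_seed_table",
    "read_jaspar",
    "read_meme",
    "find_seed_sites",
    "scan_pwm",
    "variant_mirna_gain_loss",
    "variant_tfbs_gain_loss",
    "variant_gain_loss",
]

PWM_THRESHOLD_DEFAULT = 0.85  # relative log-odds score for a TFBS hit
SCAN_REGIONS = {"5utr", "3utr", "5_upstream"}

_DNA_COMP = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


@dataclass(frozen=True)
class SeedRecord:
    """A miRNA seed: positions 2-7 of the miRNA, optionally with position 8.

    The seed is stored 5'->3' in RNA alphabet; 7 nt means positions 2-8
    (TargetScan seed-file convention "seed+m8"), 6 nt means positions 2-7.
    """

    name: str
    seed: str

    def __post_init__(self):
        s = self.seed.upper().replace("T", "U")
        object.__setattr__(self, "seed", s)
        if not 6 <= len(s) <= 7:
            raise ValueError(f"seed must be 6 or 7 nt, got {len(s)}")
        if set(s) - set("ACGU"):
            raise ValueError(f"ambiguous bases in seed {self.seed!r} of {self.name}")

    @property
    def core6_dna(self) -> str:
        """Reverse complement (DNA) of miRNA positions 2-7: the target 6mer."""
        return _revcomp(_to_dna(self.seed[:6]))

    @property
    def m8_target(self) -> str | None:
        """Target base pairing miRNA position 8, or None for 6-nt seeds."""
        if len(self.seed) == 7:
            return _to_dna(self.seed[6]).translate(_DNA_COMP)
        return None


@dataclass
class PWM:
    """Position frequency matrix with background and pseudocount."""

    name: str
    matrix: np.ndarray  # shape (4, L), rows A,C,G,T; columns sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(
            (self.matrix + self.pseudocount) / self.background[:, None]
        )

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass
class GainLossReport:
    """Gain/loss findings for one variant."""

    variant: VariantRecord
    gene_name: str
    region: str
    lost_mirna: list[tuple[str, str]] = field(default_factory=list)  # (miRNA, type)
    gained_mirna: list[tuple[str, str]] = field(default_factory=list)
    lost_tfbs: list[str] = field(default_factory=list)
    gained_tfbs: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.lost_mirna or self.gained_mirna or self.lost_tfbs or self.gained_tfbs)


# -- input parsers ---------------------------------------------------------


def read_seed_table(path) -> list[SeedRecord]:
    """Read a TargetScan-style seed file: miR family, seed+m8[, species]."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in {"mir family", "mir_family", "family"}:
                continue
            out.append(SeedRecord(name=parts[0], seed=parts[1]))
    return out


def read_jaspar(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read PWMs from a JASPAR-format motif file via Bio.motifs."""
    from Bio import motifs

    out = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            freqs = counts / counts.sum(axis=0)
            out.append(PWM(name=m.name or m.matrix_id, matrix=freqs, pseudocount=pseudocount))
    return out


def read_meme(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read PWMs from a MEME minimal-format file via Bio.motifs."""
    from Bio import motifs

    with open(path) as fh:
        record = motifs.parse(fh, "minimal")
    out = []
    for m in record:
        freqs = np.array([m.pwm[b] for b in _BASES], dtype=float)
        out.append(PWM(name=m.name, matrix=freqs, pseudocount=pseudocount))
    return out


# -- seed matching ---------------------------------------------------------


def find_seed_sites(sequence: str, seed: SeedRecord) -> list[tuple[int, str]]:
    """All seed-match sites of a miRNA in a target sequence.

    A site exists wherever the sequence contains the reverse complement of
    the 6-nt seed (miRNA positions 2-7).  Site classes: ``8mer`` (match to
    position 8 plus an A opposite position 1), ``7mer-m8`` (position-8 match
    only), ``7mer-A1`` (A only), ``6mer`` (neither).  The strongest class is
    reported per locus; positions are the 1-based start of the 6mer core.
    """
    seq = _to_dna(sequence)
    core = seed.core6_dna
    m8 = seed.m8_target
    hits = []
    start = 0
    while True:
        i = seq.find(core, start)
        if i < 0:
            break
        has_m8 = m8 is not None and i > 0 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site = "8mer"
        elif has_m8:
            site = "7mer-m8"
        elif has_a1:
            site = "7mer-A1"
        else:
            site = "6mer"
        hits.append((i + 1, site))
        start = i + 1
    return hits


# -- PWM scanning ----------------------------------------------------------


def scan_pwm(
    sequence: str, pwm: PWM, threshold: float = PWM_THRESHOLD_DEFAULT
) -> list[tuple[int, str, float]]:
    """Scan both strands of a sequence with a PWM.

    The raw score of a window is the sum of per-position log2 odds
    ``log2((f + pseudocount) / background)``; a hit is reported when the
    relative score ``(score - min) / (max - min)`` reaches ``threshold``.
    Degenerate matrices with ``max == min`` yield no hits.  Returns
    ``(position, strand, relative_score)`` with 1-based window starts.
    """
    seq = _to_dna(sequence)
    L = pwm.length
    if len(seq) < L:
        return []
    lo = pwm.log_odds
    smin = float(lo.min(axis=0).sum())
    smax = float(lo.max(axis=0).sum())
    if math.isclose(smax, smin):
        return []
    base_idx = {b: i for i, b in enumerate(_BASES)}
    hits = []
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for i in range(len(s) - L + 1):
            window = s[i : i + L]
            if any(b not in base_idx for b in window):
                continue
            score = sum(lo[base_idx[b], j] for j, b in enumerate(window))
            rel = (score - smin) / (smax - smin)
            if rel >= threshold:
                pos = i + 1 if strand == "+" else len(seq) - (i + L) + 1
                hits.append((pos, strand, rel))
    return hits


# -- variant-level gain/loss ----------------------------------------------


def _windows(model: TranscriptModel, variant: VariantRecord, radius: int):
    """Reference and alternate sequence windows (plus strand) around a variant."""
    lo = max(model.region_start, variant.position - radius)
    hi = min(
        model.region_start + len(model.region_sequence) - 1,
        variant.end + radius,
    )
    ref_window = model.region_slice(lo, hi)
    offset = variant.position - lo
    observed = ref_window[offset : offset + len(variant.ref_allele)]
    if observed != variant.ref_allele.upper():
        raise ValueError(
            f"reference allele mismatch at {variant.chromosome}:{variant.position}: "
            f"VCF says {variant.ref_allele!r}, reference has {observed!r}"
        )
    alt_window = (
        ref_window[:offset]
        + variant.alt_allele.upper()
        + ref_window[offset + len(variant.ref_allele) :]
    )
    return ref_window, alt_window


def variant_mirna_gain_loss(
    model: TranscriptModel,
    variant: VariantRecord,
    seeds: list[SeedRecord],
    region: str | None = None,
) -> GainLossReport:
    """miRNA seed sites lost/gained by a variant in UTR/upstream sequence.

    Site sets of the reference and alternate windows (radius = site length
    - 1 = 7) are compared per miRNA by site class; classes present only in
    the reference window are losses, only in the alternate gains.
    """
    region = region or classify_region(variant, model)
    report = GainLossReport(variant=variant, gene_name=model.gene_name, region=region)
    ref_w, alt_w = _windows(model, variant, radius=7)
    if model.strand == "-":
        ref_w, alt_w = _revcomp(ref_w), _revcomp(alt_w)
    for seed in seeds:
        ref_types = {t for _, t in find_seed_sites(ref_w, seed)}
        alt_types = {t for _, t in find_seed_sites(alt_w, seed)}
        for t in sorted(ref_types - alt_types):
            report.lost_mirna.append((seed.name, t))
        for t in sorted(alt_types - ref_types):
            report.gained_mirna.append((seed.name, t))
    return report


def variant_tfbs_gain_loss(
    model: TranscriptModel,
    variant: VariantRecord,
    pwms: list[PWM],
    threshold: float = PWM_THRESHOLD_DEFAULT,
    region: str | None = None,
) -> GainLossReport:
    """TFBS lost/gained by a variant: PWM hits compared between alleles.

    Windows extend ``L - 1`` beyond the variant for each motif length; a TF
    is lost when the reference window has a hit and the alternate none, and
    vice versa for gains.
    """
    region = region or classify_region(variant, model)
    report = GainLossReport(variant=variant, gene_name=model.gene_name, region=region)
    for pwm in pwms:
        ref_w, alt_w = _windows(model, variant, radius=pwm.length - 1)
        ref_hit = bool(scan_pwm(ref_w, pwm, threshold))
        alt_hit = bool(scan_pwm(alt_w, pwm, threshold))
        if ref_hit and not alt_hit:
            report.lost_tfbs.append(pwm.name)
        elif alt_hit and not ref_hit:
            report.gained_tfbs.append(pwm.name)
    return report


def variant_gain_loss(
    model: TranscriptModel,
    variant: VariantRecord,
    seeds: list[SeedRecord],
    pwms: list[PWM],
    threshold: float = PWM_THRESHOLD_DEFAULT,
) -> GainLossReport | None:
    """Combined miRNA + TFBS report; None for variants outside scanned regions."""
    region = classify_region(variant, model)
    if region not in SCAN_REGIONS:
        return None
    mi = variant_mirna_gain_loss(model, variant, seeds, region=region)
    tf = variant_tfbs_gain_loss(model, variant, pwms, threshold, region=region)
    mi.lost_tfbs = tf.lost_tfbs
    mi.gained_tfbs = tf.gained_tfbs
    return mi
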