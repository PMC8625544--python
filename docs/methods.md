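# Methods

This note documents the models and procedures implemented in `milkvar`,
the defaults they run with, and what the synthetic-data generator does and
does not emulate.

## Coordinate arithmetic and transcript models

All coordinates are 1-based, closed intervals (GFF3/VCF convention).  A
`TranscriptModel` stores exon and CDS intervals in transcription order —
descending genomic coordinates for reverse-strand genes such as *CSN2* —
together with the spliced, strand-corrected coding sequence and a cached
plus-strand window around the gene (default flank 2,000 bp) from which UTR
and upstream sequence is sliced.  `genomic_to_cds` maps a genomic position
to its 1-based position along the coding sequence in translation order, or
to one of the tags `upstream / 5utr / intron / 3utr / downstream`; the
tags partition every position of the window, and `cds_to_genomic` is its
exact inverse (asserted over all CDS positions in tests).

### Precursor vs mature numbering

Milk protein nomenclature counts residues of the mature, secreted protein.
Two offset configurations ship:

| gene | table-derived (default) | canonical signal peptide |
| --- | --- | --- |
| CSN1S1 | 15 | 15 |
| CSN2 | 50 | 15 |
| CSN1S2 | 15 | 15 |
| CSN3 | 21 | 21 |
| LALBA | 48 | 19 |
| LGB | 16 | 16 |

The defaults are derived from the printed mature/(precursor) residue pairs
of the published nomenclature tables, and for CSN2 and LALBA they differ
from the biological signal-peptide lengths.  The package does not try to
reconcile the two: the table-derived values are the default because they
reproduce the printed numbers, and `CANONICAL_OFFSETS` is available for
users who want the biological convention.  Residues at or below the offset
map to the tag `pre-mature region` (signal peptide).

## Variant handling

Multi-allelic records are split into bi-allelic records on read.
Multi-nucleotide and complex substitutions are decomposed into atomic
SNPs/InDels: equal-length records split positionally after flank trimming;
unequal lengths go through global pairwise alignment (match +1, mismatch
−1, gap −2, via Biopython's `PairwiseAligner`) followed by column
classification.  A gap run whose anchor base was itself substituted is
folded into a single atomic record so that the outputs never overlap; the
joint application of the outputs reconstructs the alternate haplotype,
property-tested over 1,000 random complex variants.

Genotype calls with known depth below 8 reads are set to missing (the
threshold is configurable; calls with unknown depth are kept).  Allele
frequencies are alternate-allele counts over 2 × non-missing animals of a
group; missing calls leave the denominator.  Display values round half
away from zero to 2 decimals, which is the convention the published
frequency tables appear to follow (their rounding rule is not stated).

Region classification yields exactly one tag per variant and transcript:
`coding`, `5utr`, `3utr`, `intron`, `5_upstream`, `3_downstream`, or
`splice_region` for non-coding positions within 8 bases into an intron or
3 bases into an exon from a junction (VEP-style windows, configurable).
Coding positions near a junction stay `coding`.  Splice effects are
flagged positionally only; no splice-strength scoring is attempted.

## Consequence prediction

The variant is applied to the spliced CDS (edits are made on the
plus-strand spliced sequence and re-oriented, so reverse-strand genes need
no special casing) after verifying the VCF reference allele against the
transcript — a mismatch is a hard error, as it almost always means the
VCF and reference disagree.  Reference and alternate products are
translated with the standard genetic code.  InDels whose length change is
not a multiple of 3 are frameshifts and are translated through the first
stop codon in the new frame, continuing into 3′-UTR exonic sequence when
the model carries it; if no stop is reached the record carries a
`no_stop` flag.

Frameshift notation `p.Xaa<n>Yaa fs*<m>` follows the milk protein
literature's convention: *m* counts the changed residues from the first
changed one (inclusive) through the last residue before the novel stop,
so the truncated product ends at *n + m − 1* and the stop codon itself
sits at new-frame position *m + 1*.  (Strict HGVS places the stop at
position *m*; the published β-LG example — 13 changed residues, product
ending at mature 104 — fixes the convention used here.)  The first
changed residue skips any leading residues unchanged by chance.  A
frameshift whose new frame opens directly on a stop codon is reported as
`stop_gained` (`p.Xaa<n>*`).  Insertions are anchored VCF-style: the
record's position is the base before the inserted sequence.

The engine is checked against an independent mutate-and-translate oracle
on random single-base InDels, and reproduces the β-LG worked example
(p.Thr92Asnfs*13, truncation at mature 104, 74 residues below the 178-AA
precursor) on a synthetic LGB transcript model.  That model is generated,
not downloaded: it is a 178-codon precursor whose exon layout places the
insertion anchor at 11:103257980 in exon 3 with offset 16, so the
published arithmetic is reproduced exactly while the filler sequence is
random.

## Allele typing

The allele catalog is data, not code: a TSV mapping each named milk
protein variant (17 across the six genes in the shipped transcription) to
its defining site alleles; users can extend it without touching the
engine.  A haplotype matches a definition only if it carries the required
allele at every defining site and the reference allele at every other
catalog site of the gene, which makes definitions mutually exclusive.
Combinations matching no definition are reported as `unresolved-novel`
with the observed site alleles attached — never force-matched to the
nearest named allele, since recognizing intermediates (such as the *LGB*
B1 form) depends on exactly this.

Animals heterozygous at more than one defining site of a gene are phased
by the EM estimator run over the gene's sites across the whole cohort;
the most probable compatible pair is reported with confidence
`em_phased`, posterior ties as `ambiguous`.  Frequencies weight each
animal's candidate pairs by their posterior, over 2 chromosomes per
resolved animal; unresolved animals (missing genotype calls at a catalog
site present in the VCF) leave the denominator.  A catalog site absent
from the VCF altogether is taken as homozygous reference for every animal
(with a warning): variant callers emit no record at an invariant site, so
treating absence as missingness would unresolve entire cohorts.

Note that maximum likelihood can disagree with the simulated truth for
individual animals: a carrier of two rare alleles in trans may be phased
in cis when that uses one common haplotype instead of two rare ones.
This is inherent to phasing from unphased genotypes, and why the
synthetic-recovery bar is ≥ 99 % rather than exact when multi-site
heterozygotes are present.

## Haplotype EM

Sites enter the casein haplotype estimation when their overall minor
allele frequency is at least 5 % (boundary inclusive), ordered by genomic
position.  Individuals missing a genotype at any selected site are
excluded from that run (expansion over missing genotypes is a possible
extension, not implemented).  Initialization is uniform over the
haplotypes observed in the compatible expansions; iteration stops when
the largest frequency change drops below 1e−8 (configurable) or after
1,000 iterations.  The log-likelihood trace is exposed and asserted
non-decreasing; on instances small enough to solve directly (≤ 3 sites,
≤ 6 individuals) the EM fixed point matches a multi-start Nelder–Mead
maximizer of the same likelihood to 1e−4.  No random restarts are run by
default; the likelihood can in principle be multimodal, and group runs
are per-breed plus pooled.  The report keeps haplotypes reaching 5 % in
at least one breed and prints frequencies to 2 dp with values below 0.01
as `<0.01`.

## Regulatory scanning

miRNA seeds follow the TargetScan seed-file convention (positions 2–8,
RNA).  A site exists where the target contains the reverse complement of
positions 2–7; an additional match opposite position 8 and/or an A
opposite position 1 upgrades the class (7mer-m8, 7mer-A1, 8mer), and the
strongest class per locus is reported.  Context scoring (AU content,
conservation) is deliberately omitted — only site presence and class are
compared between alleles.  PWMs (JASPAR or MEME minimal format, parsed
with Biopython) are scored as summed per-column log2 odds with
pseudocount 0.01 against a uniform background on both strands; a hit
requires relative score (score − min)/(max − min) ≥ 0.85 (configurable;
no threshold is published for the workflow this replaces, which was a
proprietary web service — reproducing its exact TF lists is explicitly
not a goal).  Gain/loss compares the site sets of reference and
alternate windows extending one site-length minus one beyond the variant;
per element, classes present only with the reference allele are losses
and only with the alternate gains, which makes reports exactly
anti-symmetric under allele swap.  Scans cover 5′-UTR, 3′-UTR and
upstream regions as selected by the region tag; scanning 5′-UTRs for
miRNA sites is unconventional but mirrors the study design this package
supports.

## Synthetic data generator

The generator emulates the study conditions end to end: three breed
groups of 27/20/20 animals; six genes with the real exon counts
(19/9/18/5/4/7), *CSN2* on the reverse strand; casein haplotypes drawn
per group from the published per-breed frequency columns (entries below
1 % dropped, renormalized), with rare alleles (*CSN2* L, *CSN3* K,
*CSN1S2* B) overlaid on their base haplotypes at ~1–1.5 % per chromosome;
*LALBA*/*LGB* allele pairs from the pooled frequencies; and per-call
depths uniform over 2–60 so the depth-8 filter is genuinely exercised.
Planted coding variants fix the relevant codons so every published amino
acid exchange (e.g. κ-casein Ala66Val, β-LG Ala118Val, the β-LG
frameshift) appears with its exact notation in the truth tables; planted
UTR variants create or destroy one miRNA site and one TFBS each, and UTR
filler is scrubbed of all planted motif strings so gain/loss truth is
unambiguous.  Synthetic gene lengths are free parameters: the synthetic
*CSN2* precursor is 260 codons (the real one is 224) so that the
table-derived offset of 50 can host the L variant at precursor 247 under
the same numbering the tables use.

What the generator does **not** emulate: linkage disequilibrium beyond
the casein haplotype structure, intronic/intergenic variation (only
planted variants appear in the VCF), sequencing error, genotyping bias,
or realistic depth distributions.  Passing tests therefore demonstrate
correctness of the algorithms under the stated sampling model, not
robustness to real-data artifacts.

All randomness flows from a single integer seed through one
`numpy.random.Generator` per run; identical seeds give byte-identical
FASTA/GFF3/VCF outputs.

## Problem sizes and numerical choices

The acceptance computation simulates 5,000 diploids at the four casein
loci (the published pooled frequencies 0.39/0.22/0.20/0.19 of the four
major haplotypes already sum to 1, so renormalization is a no-op) and
checks the top haplotype estimate; across seeds the estimate stays within
±0.01 of 0.39.  Test-suite replicate counts (20 EM replicates, 1,000
random decompositions/seed matches, 50 random InDels) were chosen to keep
the full suite under about two minutes on one CPU while exercising every
oracle.  Ties in EM phasing posteriors are broken by reporting
`ambiguous`; degenerate PWMs (max score = min score) yield no hits;
empty site lists skip the EM with a warning rather than failing.
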