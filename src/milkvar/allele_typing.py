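"""Named milk protein allele assignment from genotypes at catalog sites.

Milk protein variants (CSN1S1 B/C, CSN2 A1/A2/L, CSN3 A/B/K, LGB B/B1/K, ...)
are named alleles defined by specific site-allele combinations.  This module
matches each chromosome copy of each animal against a catalog of allele
definitions; animals heterozygous at more than one defining site of a gene
are phased with the EM haplotype estimator; combinations matching no
definition are reported as unresolved-novel, never force-matched.

The shipped catalog transcribes the published nomenclature table (17 named
variants across the six genes); it is data, not code, and can be extended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .haplotypes import em_haplotypes
from .variant_io import GenotypeMatrix

__all__ = [
    "AlleleDefinition",
    "AlleleCatalog",
    "TypedAllele",
    "load_catalog",
    "default_catalog_path",
    "assign_alleles",
    "allele_frequencies_by_group",
]

UNRESOLVED = "unresolved"
UNRESOLVED_NOVEL = "unresolved-novel"

Site = tuple[str, int]  # (chromosome, position)


@dataclass(frozen=True)
class AlleleDefinition:
    gene: str
    name: str
    #: site -> required allele string; sites of the gene not listed default
    #: to the reference allele
    defining_sites: dict[Site, str] = field(default_factory=dict)
    status: str = "known"

    def required_allele(self, site: Site, ref: str) -> str:
        return self.defining_sites.get(site, ref)


@dataclass
class AlleleCatalog:
    #: gene -> allele name -> definition
    definitions: dict[str, dict[str, AlleleDefinition]]
    #: gene -> site -> (ref allele, alt allele)
    sites: dict[str, dict[Site, tuple[str, str]]]
    #: gene -> site -> variant id (rs#/ss#), informational
    ids: dict[str, dict[Site, str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.definitions)

    def gene_sites(self, gene: str) -> list[Site]:
        return sorted(self.sites[gene], key=lambda s: (s[0], s[1]))

    def n_alleles(self) -> int:
        return sum(len(d) for d in self.definitions.values())

    def match(self, gene: str, haplotype: dict[Site, str]) -> str | None:
        """Name of the unique definition consistent with a full site-allele
        assignment, or None."""
        for name, definition in self.definitions[gene].items():
            ok = all(
                haplotype[site] == definition.required_allele(site, ref)
                for site, (ref, _alt) in self.sites[gene].items()
            )
            if ok:
                return name
        return None


def default_catalog_path():
    """Path of the shipped allele-definition catalog."""
    return resources.files("milkvar.data") / "allele_catalog.tsv"


def load_catalog(path=None) -> AlleleCatalog:
    """Load an allele catalog from TSV.

    Columns: gene, allele_name, chrom, pos, ref, alt, required_allele,
    status[, id].  Raises on an empty file, on conflicting duplicate rows,
    and on two alleles of a gene with identical defining site-allele sets.
    """
    path = path or default_catalog_path()
    rows = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "gene":
                continue
            if len(parts) < 8:
                raise ValueError(f"malformed catalog row: {line!r}")
            rows.append(parts)
    if not rows:
        raise ValueError(f"allele catalog {path} is empty")

    sites: dict[str, dict[Site, tuple[str, str]]] = {}
    ids: dict[str, dict[Site, str]] = {}
    requirements: dict[tuple[str, str], dict[Site, str]] = {}
    status: dict[tuple[str, str], str] = {}
    for parts in rows:
        gene, name, chrom, pos, ref, alt, required = parts[:7]
        st = parts[7]
        site = (chrom, int(pos))
        known = sites.setdefault(gene, {})
        if site in known and known[site] != (ref, alt):
            raise ValueError(f"conflicting ref/alt for site {site} in gene {gene}")
        known[site] = (ref, alt)
        if len(parts) > 8:
            ids.setdefault(gene, {})[site] = parts[8]
        key = (gene, name)
        req = requirements.setdefault(key, {})
        if site in req and req[site] != required:
            raise ValueError(
                f"duplicate conflicting requirement for allele {name} of {gene} at {site}"
            )
        req[site] = required
        status[key] = st

    definitions: dict[str, dict[str, AlleleDefinition]] = {}
    for (gene, name), req in requirements.items():
        non_ref = {
            site: allele
            for site, allele in req.items()
            if allele != sites[gene][site][0]
        }
        definitions.setdefault(gene, {})[name] = AlleleDefinition(
            gene=gene, name=name, defining_sites=non_ref, status=status[(gene, name)]
        )

    # no two alleles of a gene may share an identical site-allele set
    for gene, defs in definitions.items():
        seen: dict[frozenset, str] = {}
        for name, definition in defs.items():
            key = frozenset(definition.defining_sites.items())
            if key in seen:
                raise ValueError(
                    f"alleles {seen[key]} and {name} of {gene} share identical "
                    "defining site-allele sets"
                )
            seen[key] = name
    return AlleleCatalog(definitions=definitions, sites=sites, ids=ids)


@dataclass
class TypedAllele:
    """Per-animal milk protein allele assignment for one gene."""

    animal_id: str
    group: str
    gene: str
    #: canonical (alphabetical) pair of allele names, or (UNRESOLVED,)*2
    pair: tuple[str, str]
    phase_confidence: str  # exact | em_phased | ambiguous | unresolved
    #: posterior weights over candidate name pairs (canonical order)
    posterior: dict[tuple[str, str], float] = field(default_factory=dict)
    #: observed site-allele sets for unresolved-novel haplotypes
    novel_haplotypes: list[dict[Site, str]] = field(default_factory=list)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def assign_alleles(
    catalog: AlleleCatalog, matrix: GenotypeMatrix, gene: str
) -> list[TypedAllele]:
    """Assign named allele pairs for ``gene`` to every animal in the matrix.

    Catalog sites absent from the VCF are taken as homozygous reference in
    every animal (a caller emits no record at an invariant site); animals
    with a missing genotype call at a present site are flagged unresolved.
    Heterozygosity at more than one defining site is phased with the EM
    estimator over the gene's sites; residual ties are flagged ambiguous.
    """
    gene_sites = catalog.gene_sites(gene)
    site_to_var: dict[Site, int | None] = {}
    for site in gene_sites:
        chrom, pos = site
        ref, alt = catalog.sites[gene][site]
        try:
            site_to_var[site] = matrix.variant_index(chrom, pos, alt)
        except KeyError:
            site_to_var[site] = None
            warnings.warn(
                f"catalog site {chrom}:{pos} ({gene}) absent from VCF; "
                "assuming homozygous reference"
            )

    present = [s for s in gene_sites if site_to_var[s] is not None]
    present_idx = [site_to_var[s] for s in present]

    # one EM run over the gene's polymorphic sites for phasing multi-het animals
    em = None
    if len(present) >= 2:
        try:
            em = em_haplotypes(matrix, present_idx)
        except ValueError:
            em = None
    em_pos = {aid: i for i, aid in enumerate(em.individual_ids)} if em else {}

    out: list[TypedAllele] = []
    for j, (animal_id, group) in enumerate(matrix.animals):
        genotype: dict[Site, tuple[int, int] | None] = {}
        unresolved = False
        for site in gene_sites:
            vi = site_to_var[site]
            if vi is None:
                genotype[site] = (0, 0)
                continue
            a, b = matrix.genotypes[vi, j]
            if a < 0 or b < 0:
                unresolved = True
                break
            genotype[site] = (int(a), int(b))
        if unresolved:
            out.append(
                TypedAllele(animal_id, group, gene, (UNRESOLVED, UNRESOLVED), UNRESOLVED)
            )
            continue

        het_sites = [s for s in gene_sites if sum(genotype[s]) == 1]
        candidate_pairs: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
        weights: list[float] = []
        if len(het_sites) <= 1:
            h1 = tuple(min(genotype[s]) for s in gene_sites)
            h2 = tuple(max(genotype[s]) for s in gene_sites)
            candidate_pairs = [(h1, h2)]
            weights = [1.0]
            confidence = "exact"
        else:
            confidence = "em_phased"
            pairs_w = _em_pairs_for(
                em, em_pos.get(animal_id), present, gene_sites, genotype
            )
            if pairs_w is None:  # EM unavailable: enumerate uniformly
                pairs_w = _uniform_pairs(gene_sites, genotype)
                confidence = "ambiguous"
            candidate_pairs = [p for p, _ in pairs_w]
            weights = [w for _, w in pairs_w]
            top = max(weights)
            if sum(1 for w in weights if np.isclose(w, top, atol=1e-9)) > 1:
                confidence = "ambiguous"

        # translate best pair (and posteriors) into allele names
        named_posterior: dict[tuple[str, str], float] = {}
        novel: list[dict[Site, str]] = []
        for (h1, h2), w in zip(candidate_pairs, weights):
            n1 = _name_of(catalog, gene, gene_sites, h1, novel)
            n2 = _name_of(catalog, gene, gene_sites, h2, novel)
            key = _canonical(n1, n2)
            named_posterior[key] = named_posterior.get(key, 0.0) + w
        best = max(named_posterior, key=named_posterior.get)
        out.append(
            TypedAllele(
                animal_id,
                group,
                gene,
                best,
                confidence,
                posterior=named_posterior,
                novel_haplotypes=novel,
            )
        )
    return out


def _name_of(catalog, gene, gene_sites, hap: tuple[int, ...], novel_sink) -> str:
    alleles = {}
    for site, bit in zip(gene_sites, hap):
        ref, alt = catalog.sites[gene][site]
        alleles[site] = alt if bit else ref
    name = catalog.match(gene, alleles)
    if name is None:
        novel_sink.append(alleles)
        return UNRESOLVED_NOVEL
    return name


def _uniform_pairs(gene_sites, genotype):
    from .haplotypes import _compatible_pairs

    row = np.array([sum(genotype[s]) for s in gene_sites])
    pairs = _compatible_pairs(row)
    w = 1.0 / len(pairs)
    return [((h1, h2), w) for h1, h2 in pairs]


def _em_pairs_for(em, em_i, present, gene_sites, genotype):
    """Posterior pairs from the gene-level EM run, expanded to all gene sites."""
    if em is None or em_i is None:
        return None
    present_set = set(present)
    fixed = {s: genotype[s][0] for s in gene_sites if s not in present_set}
    out = []
    for (a, b), w in em.posteriors[em_i]:
        hap_a = em.haplotypes[a]
        hap_b = em.haplotypes[b]
        full_a = tuple(
            fixed[s] if s not in present_set else hap_a[present.index(s)]
            for s in gene_sites
        )
        full_b = tuple(
            fixed[s] if s not in present_set else hap_b[present.index(s)]
            for s in gene_sites
        )
        out.append(((full_a, full_b), w))
    return out


def allele_frequencies_by_group(
    typed: list[TypedAllele], groups: list[str] | None = None
) -> pd.DataFrame:
    """Allele frequencies per gene x allele x group (plus "Total").

    Each resolved animal contributes posterior-weighted allele counts over
    2 chromosomes; unresolved animals are excluded from the denominator.
    Within a gene and group the frequencies (including unresolved-novel)
    sum to 1 over the resolved fraction.
    """
    if groups is None:
        seen: dict[str, None] = {}
        for t in typed:
            seen.setdefault(t.group)
        groups = list(seen)
    counts: dict[tuple[str, str, str], float] = {}
    denom: dict[tuple[str, str], float] = {}
    for t in typed:
        if t.phase_confidence == UNRESOLVED:
            continue
        for g in (t.group, "Total"):
            denom[(t.gene, g)] = denom.get((t.gene, g), 0.0) + 2.0
            for (n1, n2), w in (t.posterior or {t.pair: 1.0}).items():
                for n in (n1, n2):
                    counts[(t.gene, n, g)] = counts.get((t.gene, n, g), 0.0) + w
    records = []
    for (gene, allele, group), c in counts.items():
        records.append(
            {
                "gene": gene,
                "allele": allele,
                "group": group,
                "frequency": c / denom[(gene, group)],
            }
        )
    df = pd.DataFrame.from_records(records)
    if df.empty:
        return df
    wide = df.pivot_table(
        index=["gene", "allele"], columns="group", values="frequency", fill_value=0.0
    )
    ordered = [g for g in groups if g in wide.columns] + ["Total"]
    return wide[ordered]
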