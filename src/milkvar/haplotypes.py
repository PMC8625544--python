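"""EM estimation of multilocus haplotype frequencies from unphased genotypes.

The casein genes CSN1S1-CSN2-CSN1S2-CSN3 sit in a tight cluster on bovine
chromosome 6 and are inherited as haplotypes.  Given unphased diploid
genotypes at a set of bi-allelic sites, the expectation-maximization
algorithm iterates between (E) assigning each individual posterior weights
over the haplotype pairs compatible with its genotype, proportional to
p_h1 * p_h2 (doubled for heterozygous pairs), and (M) setting each
haplotype frequency to its expected allele count over 2n chromosomes.  The
observed-data log-likelihood is non-decreasing at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, allele_frequency

__all__ = [
    "EMResult",
    "HaplotypeTable",
    "select_sites",
    "em_haplotypes",
    "group_haplotype_frequencies",
    "format_frequency",
]

MAF_THRESHOLD_DEFAULT = 0.05  # minimum overall minor-allele frequency
DISPLAY_FLOOR = 0.01  # frequencies below this print as "<0.01"


@dataclass
class EMResult:
    """Outcome of one EM run."""

    haplotypes: list[tuple[int, ...]]  # allele vectors (0=ref, 1=alt per site)
    frequencies: np.ndarray
    loglik_trace: list[float]
    iterations: int
    converged: bool
    #: per retained individual: list of ((hap_index_a, hap_index_b), weight)
    posteriors: list[list[tuple[tuple[int, int], float]]]
    individual_ids: list[str] = field(default_factory=list)

    def frequency_of(self, hap: tuple[int, ...]) -> float:
        return float(self.frequencies[self.haplotypes.index(hap)])

    def top(self) -> tuple[tuple[int, ...], float]:
        i = int(np.argmax(self.frequencies))
        return self.haplotypes[i], float(self.frequencies[i])


@dataclass
class HaplotypeTable:
    """Haplotype frequency estimates per group plus the pooled estimate."""

    sites: list[int]  # variant indices of the sites used
    labels: list[str]  # haplotype labels, e.g. "B-A1-A-B"
    table: pd.DataFrame  # rows=labels, columns=groups + "Total"
    results: dict[str, EMResult] = field(default_factory=dict)


def select_sites(
    matrix: GenotypeMatrix,
    candidate_indices: list[int] | None = None,
    maf_threshold: float = MAF_THRESHOLD_DEFAULT,
) -> list[int]:
    """Variant indices with overall minor-allele frequency >= threshold.

    The returned list is ordered by genomic position (chromosome, then bp).
    """
    indices = (
        list(range(matrix.n_variants)) if candidate_indices is None else candidate_indices
    )
    kept = []
    for i in indices:
        freq, _ = allele_frequency(matrix, i, "ALL")
        if freq is None:
            continue
        if min(freq, 1.0 - freq) >= maf_threshold:
            kept.append(i)
    kept.sort(key=lambda i: (matrix.variants[i].chromosome, matrix.variants[i].position))
    if not kept:
        warnings.warn("no sites pass the MAF threshold; haplotype estimation skipped")
    return kept


# -- core EM ---------------------------------------------------------------


def _compatible_pairs(genotype: np.ndarray):
    """All unordered haplotype pairs compatible with one unphased genotype.

    ``genotype`` holds per-site alt-allele counts (0/1/2).  Heterozygous
    sites double the expansion; the first het site is pinned to break the
    mirror symmetry so pairs are enumerated once.
    """
    het = np.flatnonzero(genotype == 1)
    base = (genotype // 2).astype(int)
    base[het] = 0
    if het.size == 0:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    free = het[1:]
    for bits in product((0, 1), repeat=free.size):
        h1 = base.copy()
        h2 = base.copy()
        h1[het[0]] = 0
        h2[het[0]] = 1
        for site, bit in zip(free, bits):
            h1[site] = bit
            h2[site] = 1 - bit
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotypes(
    matrix: GenotypeMatrix,
    sites: list[int],
    tol: float = 1e-8,
    max_iter: int = 1000,
    animal_indices: np.ndarray | None = None,
) -> EMResult:
    """Maximum-likelihood haplotype frequencies at ``sites`` by EM.

    Individuals with a missing genotype at any selected site are excluded.
    Initialization is uniform over the haplotypes observed in the compatible
    expansions; convergence when the largest frequency change drops below
    ``tol`` or after ``max_iter`` iterations.
    """
    if not sites:
        raise ValueError("no sites supplied")
    cols = (
        np.arange(matrix.n_animals) if animal_indices is None else np.asarray(animal_indices)
    )
    g = matrix.genotypes[np.ix_(sites, cols)]  # (n_sites, n_ind, 2)
    complete = (g >= 0).all(axis=(0, 2))
    if not complete.any():
        raise ValueError("no individuals with complete genotypes at the selected sites")
    g = g[:, complete].sum(axis=2).T  # (n_ind, n_sites) alt-allele counts
    kept_ids = [matrix.animals[c][0] for c, ok in zip(cols, complete) if ok]

    pair_lists = [_compatible_pairs(row) for row in g]
    hap_index: dict[tuple[int, ...], int] = {}
    for pairs in pair_lists:
        for h1, h2 in pairs:
            hap_index.setdefault(h1, len(hap_index))
            hap_index.setdefault(h2, len(hap_index))
    haplotypes = list(hap_index)
    H = len(haplotypes)
    idx_pairs = [
        [(hap_index[h1], hap_index[h2]) for h1, h2 in pairs] for pairs in pair_lists
    ]

    p = np.full(H, 1.0 / H)
    trace: list[float] = []
    converged = False
    it = 0
    posteriors: list[list[tuple[tuple[int, int], float]]] = []
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        loglik = 0.0
        posteriors = []
        for pairs in idx_pairs:
            w = np.array(
                [p[a] * p[b] * (1.0 if a == b else 2.0) for a, b in pairs]
            )
            total = w.sum()
            loglik += np.log(total) if total > 0 else -np.inf
            if total <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
            else:
                w = w / total
            posteriors.append(list(zip(pairs, w.tolist())))
            for (a, b), weight in zip(pairs, w):
                counts[a] += weight
                counts[b] += weight
        new_p = counts / (2.0 * len(idx_pairs))
        trace.append(float(loglik))
        delta = float(np.max(np.abs(new_p - p)))
        p = new_p
        if delta < tol:
            converged = True
            break
    return EMResult(
        haplotypes=haplotypes,
        frequencies=p,
        loglik_trace=trace,
        iterations=it,
        converged=converged,
        posteriors=posteriors,
        individual_ids=kept_ids,
    )


def loglikelihood(genotype_rows: np.ndarray, haplotypes, frequencies) -> float:
    """Observed-data log-likelihood of haplotype frequencies (shared by tests)."""
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    ll = 0.0
    for row in genotype_rows:
        s = 0.0
        for h1, h2 in _compatible_pairs(np.asarray(row)):
            if h1 in hap_index and h2 in hap_index:
                p1 = frequencies[hap_index[h1]]
                p2 = frequencies[hap_index[h2]]
                s += p1 * p2 * (1.0 if h1 == h2 else 2.0)
        ll += np.log(s) if s > 0 else -np.inf
    return float(ll)


# -- grouped runs and reporting -------------------------------------------


def format_frequency(freq: float, floor: float = DISPLAY_FLOOR) -> str:
    """Table-style display: 2 dp, with values below the floor as "<0.01"."""
    if 0.0 < freq < floor:
        return f"<{floor:.2f}"
    from .variant_io import round_half_away

    return f"{round_half_away(freq, 2):.2f}"


def group_haplotype_frequencies(
    matrix: GenotypeMatrix,
    sites: list[int],
    labeler=None,
    min_group_size: int = 2,
    min_display_freq: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeTable:
    """One EM run per group plus a pooled run over all animals.

    ``labeler`` maps a haplotype allele vector to a display label (e.g.
    catalog allele names joined as "B-A1-A-B"); defaults to the raw 0/1
    vector.  The returned table keeps haplotypes reaching
    ``min_display_freq`` in at least one group, sorted by pooled frequency.
    """
    labeler = labeler or (lambda hap: "-".join(map(str, hap)))
    results: dict[str, EMResult] = {}
    groups = matrix.groups
    for group in groups:
        cols = matrix.group_indices(group)
        if cols.size < min_group_size:
            warnings.warn(f"group {group!r} below minimum size; skipped")
            continue
        results[group] = em_haplotypes(matrix, sites, tol, max_iter, cols)
    results["Total"] = em_haplotypes(matrix, sites, tol, max_iter)

    all_haps: dict[tuple[int, ...], None] = {}
    for res in results.values():
        for h in res.haplotypes:
            all_haps.setdefault(h)
    rows = {}
    for hap in all_haps:
        freqs = {}
        for name, res in results.items():
            freqs[name] = (
                res.frequency_of(hap) if hap in res.haplotypes else 0.0
            )
        rows[labeler(hap)] = freqs
    table = pd.DataFrame.from_dict(rows, orient="index")
    col_order = [g for g in groups if g in table.columns] + ["Total"]
    table = table[col_order]
    breed_cols = [c for c in table.columns if c != "Total"] or ["Total"]
    keep = (table[breed_cols] >= min_display_freq).any(axis=1)
    table = table[keep].sort_values("Total", ascending=False)
    return HaplotypeTable(
        sites=list(sites), labels=list(table.index), table=table, results=results
    )
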