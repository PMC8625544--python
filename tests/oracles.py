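"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected result by a different route than the
implementation under test: exhaustive enumeration, direct optimization or
naive re-translation.
"""

import itertools

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# -- haplotype likelihood maximization ------------------------------------


def all_haplotypes(n_sites: int):
    return list(itertools.product((0, 1), repeat=n_sites))


def genotype_loglik(genotypes: np.ndarray, freqs: dict) -> float:
    """Log-likelihood of unphased genotype rows under haplotype frequencies."""
    ll = 0.0
    n_sites = genotypes.shape[1]
    haps = all_haplotypes(n_sites)
    for row in genotypes:
        s = 0.0
        for h1 in haps:
            for h2 in haps:
                if all(a + b == g for a, b, g in zip(h1, h2, row)):
                    s += freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
        ll += np.log(s) if s > 0 else -np.inf
    return float(ll)


def brute_force_ml(genotypes: np.ndarray, n_starts: int = 40, seed: int = 0):
    """Best log-likelihood over the haplotype frequency simplex.

    Multi-start Nelder-Mead on a softmax parameterization; independent of
    the EM implementation.
    """
    from scipy.optimize import minimize

    n_sites = genotypes.shape[1]
    haps = all_haplotypes(n_sites)
    rng = np.random.default_rng(seed)

    def neg_ll(theta):
        w = np.exp(theta - theta.max())
        p = w / w.sum()
        freqs = dict(zip(haps, p))
        return -genotype_loglik(genotypes, freqs)

    best = np.inf
    for _ in range(n_starts):
        x0 = rng.normal(size=len(haps))
        res = minimize(neg_ll, x0, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-10})
        best = min(best, res.fun)
    return -best


# -- seed matching by exhaustive window enumeration ------------------------


def enumerate_seed_sites(sequence: str, seed_rna: str):
    """All (position, site_type) by checking every window explicitly."""
    seq = sequence.upper().replace("U", "T")
    seed = seed_rna.upper().replace("T", "U")
    core = revcomp(seed[:6].replace("U", "T"))
    m8 = seed[6].replace("U", "T").translate(_COMP) if len(seed) == 7 else None
    hits = []
    for i in range(len(seq) - 5):
        if seq[i : i + 6] != core:
            continue
        has_m8 = m8 is not None and i >= 1 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            t = "8mer"
        elif has_m8:
            t = "7mer-m8"
        elif has_a1:
            t = "7mer-A1"
        else:
            t = "6mer"
        hits.append((i + 1, t))
    return hits


# -- PWM scoring by per-column summation -----------------------------------


def pwm_window_score(window: str, matrix: np.ndarray, background: np.ndarray, pseudo: float):
    """Raw log2-odds of one window, summed column by column."""
    idx = {b: i for i, b in enumerate("ACGT")}
    total = 0.0
    for j, b in enumerate(window):
        total += np.log2((matrix[idx[b], j] + pseudo) / background[idx[b]])
    return total


# -- naive mutate-and-translate consequence oracle --------------------------

_CODON = {}


def translate(seq: str, through_stop: bool = True) -> str:
    from Bio.Seq import Seq

    usable = seq[: len(seq) - len(seq) % 3]
    prot = str(Seq(usable).translate())
    if through_stop and "*" in prot:
        return prot[: prot.index("*") + 1]
    return prot


def indel_consequence(cds: str, pos0: int, ref: str, alt: str):
    """(kind, first_changed_precursor, terminal_offset_or_None) for an edit
    of the coding sequence at 0-based position ``pos0``."""
    assert cds[pos0 : pos0 + len(ref)] == ref
    mutated = cds[:pos0] + alt + cds[pos0 + len(ref) :]
    ref_prot = translate(cds, through_stop=False)
    alt_prot = translate(mutated, through_stop=True)
    delta = len(alt) - len(ref)
    first = None
    for i, (a, b) in enumerate(zip(ref_prot, alt_prot)):
        if a != b:
            first = i
            break
    if first is None and len(ref_prot) != len(alt_prot):
        first = min(len(ref_prot), len(alt_prot))
    if delta % 3 != 0:
        if first is None:
            first = min(len(ref_prot), len(alt_prot)) - 1
        stop = alt_prot.find("*")
        terminal = (stop - first) if stop >= 0 else None
        if terminal == 0:  # new frame opens directly on a stop codon
            return "stop_gained", first + 1, None
        return "frameshift", first + 1, terminal
    if first is None:
        return "synonymous", None, None
    if delta == 0:
        return ("stop_gained" if alt_prot[first] == "*" else "missense"), first + 1, None
    return "inframe_indel", first + 1, None
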