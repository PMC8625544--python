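"""Seed matching, PWM scanning and variant gain/loss reports."""

import numpy as np
import pytest

import oracles
from milkvar.regulatory_scan import (
    PWM,
    SeedRecord,
    find_seed_sites,
    read_jaspar,
    read_seed_table,
    scan_pwm,
    variant_mirna_gain_loss,
    variant_tfbs_gain_loss,
)
from milkvar.variant_io import VariantRecord


class TestSeedRecord:
    def test_rna_normalization_and_lengths(self):
        s = SeedRecord("x", "AGTCGTA")
        assert s.seed == "AGUCGUA"
        assert s.core6_dna == oracles.revcomp("AGTCGT")
        assert s.m8_target == "T"

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            SeedRecord("x", "AGUCNUA")

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            SeedRecord("x", "AGUC")


class TestFindSeedSites:
    seed = SeedRecord("mir", "AGUCGUA")  # core6 = ACGACT, m8 target T

    def test_planted_8mer(self):
        seq = "GGGG" + "T" + "ACGACT" + "A" + "GGGG"
        assert find_seed_sites(seq, self.seed) == [(6, "8mer")]

    def test_7mer_a1_when_m8_mismatches(self):
        seq = "GGGG" + "C" + "ACGACT" + "A" + "GGGG"
        assert find_seed_sites(seq, self.seed) == [(6, "7mer-A1")]

    def test_7mer_m8_without_a1(self):
        seq = "GGGG" + "T" + "ACGACT" + "G" + "GGGG"
        assert find_seed_sites(seq, self.seed) == [(6, "7mer-m8")]

    def test_bare_6mer(self):
        seq = "GGGG" + "C" + "ACGACT" + "G" + "GGGG"
        assert find_seed_sites(seq, self.seed) == [(6, "6mer")]

    def test_random_sequence_without_complement_is_empty(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("AG"), 200))  # cannot contain ACGACT
        assert find_seed_sites(seq, self.seed) == []

    def test_matches_exhaustive_enumeration_on_random_pairs(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            seq = "".join(rng.choice(bases, int(rng.integers(10, 60))))
            seed_len = int(rng.integers(6, 8))
            seed = "".join(rng.choice(bases, seed_len)).replace("T", "U")
            record = SeedRecord("r", seed)
            assert find_seed_sites(seq, record) == oracles.enumerate_seed_sites(seq, seed)


def sharp_pwm(consensus: str, name="TF") -> PWM:
    matrix = np.full((4, len(consensus)), 0.03)
    for j, b in enumerate(consensus):
        matrix["ACGT".index(b), j] = 0.91
    return PWM(name=name, matrix=matrix)


class TestScanPwm:
    def test_consensus_scores_relative_one(self):
        pwm = sharp_pwm("TTCCAG")
        hits = scan_pwm("AAAA" + "TTCCAG" + "AAAA", pwm, threshold=0.99)
        plus = [h for h in hits if h[1] == "+"]
        assert plus and plus[0][0] == 5
        assert plus[0][2] == pytest.approx(1.0)

    def test_uniform_pwm_yields_no_hits(self):
        pwm = PWM(name="flat", matrix=np.full((4, 6), 0.25))
        assert scan_pwm("ACGTACGTACGT", pwm, threshold=0.0) == []

    def test_reverse_strand_hit(self):
        pwm = sharp_pwm("TTCCAG")
        seq = "AAAA" + oracles.revcomp("TTCCAG") + "AAAA"
        hits = scan_pwm(seq, pwm, threshold=0.99)
        assert any(strand == "-" for _, strand, _ in hits)

    def test_scores_match_per_column_summation_oracle(self):
        rng = np.random.default_rng(21)
        raw = rng.random((4, 8))
        matrix = raw / raw.sum(axis=0)
        pwm = PWM(name="r", matrix=matrix, pseudocount=0.01)
        lo = pwm.log_odds
        smin, smax = lo.min(axis=0).sum(), lo.max(axis=0).sum()
        for _ in range(100):
            window = "".join(rng.choice(list("ACGT"), 8))
            expected_raw = oracles.pwm_window_score(window, matrix, pwm.background, 0.01)
            expected_rel = (expected_raw - smin) / (smax - smin)
            hits = scan_pwm(window, pwm, threshold=-1.0)
            plus = {p: r for p, s, r in hits if s == "+"}
            assert plus[1] == pytest.approx(expected_rel, abs=1e-9)


class TestVariantGainLoss:
    def test_planted_site_destroyed_is_a_loss(self, synthetic_models, synthetic_bundle):
        reference, _ = synthetic_bundle
        seeds = read_seed_table(reference.seeds_path)
        planted = [v for v in reference.planted if v.mirna_loss]
        assert planted
        for v in planted:
            rec = VariantRecord(v.chromosome, v.position, v.ref, v.alt)
            report = variant_mirna_gain_loss(synthetic_models[v.gene], rec, seeds)
            assert [n for n, _ in report.lost_mirna] == [n for n, _ in v.mirna_loss]
            assert report.gained_mirna == []

    def test_variant_outside_any_site_is_empty(self, toy_model):
        seeds = [SeedRecord("mir", "AGUCGUA")]
        rec = VariantRecord("chrT", 15, "T", "C")  # 5'UTR, all-T neighbourhood
        report = variant_mirna_gain_loss(toy_model, rec, seeds)
        assert report.lost_mirna == [] and report.gained_mirna == []

    def test_allele_swap_antisymmetry_mirna(self, synthetic_models, synthetic_bundle):
        reference, _ = synthetic_bundle
        seeds = read_seed_table(reference.seeds_path)
        for v in reference.planted:
            if v.kind != "utr_snp":
                continue
            model = synthetic_models[v.gene]
            fwd = variant_mirna_gain_loss(
                model, VariantRecord(v.chromosome, v.position, v.ref, v.alt), seeds
            )
            # swapping alleles needs the alternate as "reference" sequence:
            # patch the cached region so the swap is well-defined
            swapped_model = _with_alt_base(model, v.position, v.alt)
            rev = variant_mirna_gain_loss(
                swapped_model, VariantRecord(v.chromosome, v.position, v.alt, v.ref), seeds
            )
            assert sorted(fwd.lost_mirna) == sorted(rev.gained_mirna)
            assert sorted(fwd.gained_mirna) == sorted(rev.lost_mirna)

    def test_allele_swap_antisymmetry_tfbs(self, synthetic_models, synthetic_bundle):
        reference, _ = synthetic_bundle
        pwms = read_jaspar(reference.pwms_path)
        for v in reference.planted:
            if v.kind != "utr_snp":
                continue
            model = synthetic_models[v.gene]
            fwd = variant_tfbs_gain_loss(
                model, VariantRecord(v.chromosome, v.position, v.ref, v.alt), pwms
            )
            swapped_model = _with_alt_base(model, v.position, v.alt)
            rev = variant_tfbs_gain_loss(
                swapped_model, VariantRecord(v.chromosome, v.position, v.alt, v.ref), pwms
            )
            assert sorted(fwd.lost_tfbs) == sorted(rev.gained_tfbs)
            assert sorted(fwd.gained_tfbs) == sorted(rev.lost_tfbs)

    def test_planted_tfbs_gain_recovered(self, synthetic_models, synthetic_bundle):
        reference, _ = synthetic_bundle
        pwms = read_jaspar(reference.pwms_path)
        planted = [v for v in reference.planted if v.tfbs_gain]
        assert planted
        for v in planted:
            rec = VariantRecord(v.chromosome, v.position, v.ref, v.alt)
            report = variant_tfbs_gain_loss(synthetic_models[v.gene], rec, pwms)
            assert report.gained_tfbs == v.tfbs_gain
            assert report.lost_tfbs == []


def _with_alt_base(model, position, alt):
    """Copy of a model whose cached region carries the alternate base."""
    import copy

    m = copy.copy(model)
    idx = position - model.region_start
    seq = model.region_sequence
    m.region_sequence = seq[:idx] + alt + seq[idx + 1 :]
    return m
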