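"""Divisive denoiser: error model, abundance statistic, partitioning, bimeras."""

import math

import numpy as np
import pytest

from v9var.denoise import (
    ASV,
    DenoiseConfig,
    ErrorModel,
    UniqueSeq,
    abundance_p_value,
    denoise_paired,
    denoise_reads,
    denoise_sample,
    dereplicate_with_quality,
    error_probability,
    learn_error_model,
    remove_bimeras_consensus,
)
from v9var.readprep import Read
from v9var.simulate import SimConfig, pairs_from_reads, simulate_genome_reads

from conftest import mutate, random_seq

NOERR = {q: 0.0 for q in range(94)}


def _uniform_model(rate_at_q30=1e-3):
    """Model with a flat per-target substitution probability at every quality."""
    p = np.zeros((4, 4, 94))
    for a in range(4):
        for b in range(4):
            p[a, b, :] = rate_at_q30 if a != b else 1.0 - 3 * rate_at_q30
    return ErrorModel(p)


def _unique(seq, count, q=30):
    return UniqueSeq(seq, count, np.full(len(seq), q, dtype=int))


class TestErrorProbability:
    def test_identical_to_center_is_near_one(self, rng):
        seq = random_seq(rng, 100)
        rho = error_probability(_unique(seq, 10), seq, _uniform_model(1e-3))
        assert rho == pytest.approx((1 - 3e-3) ** 100)

    def test_single_substitution_single_factor(self, rng):
        center = random_seq(rng, 100)
        variant = mutate(rng, center, 1)
        rho = error_probability(_unique(variant, 1), center, _uniform_model(1e-3))
        assert rho == pytest.approx(1e-3 * (1 - 3e-3) ** 99)

    def test_two_substitutions_product_rule(self, rng):
        center = random_seq(rng, 100)
        variant = mutate(rng, center, 2)
        rho = error_probability(_unique(variant, 1), center, _uniform_model(1e-3))
        # explicit multiplication oracle
        assert rho == pytest.approx(1e-3 * 1e-3 * (1 - 3e-3) ** 98)

    def test_indel_uses_configured_event_probability(self, rng):
        center = random_seq(rng, 100)
        variant = center[:50] + center[51:]  # one deletion
        cfg = DenoiseConfig(indel_prob=1e-4)
        rho = error_probability(_unique(variant, 1), center, _uniform_model(1e-3), cfg)
        assert rho == pytest.approx(1e-4 * (1 - 3e-3) ** 99, rel=0.05)


class TestAbundancePValue:
    def test_singleton_is_one(self):
        for lam in (0.0, 1e-6, 1.0, 100.0):
            assert abundance_p_value(1, lam) == 1.0

    def test_against_independent_tail_sum(self):
        """Closed form P(X>=n)/P(X>=1) for Poisson, summed term by term."""
        lam, n = 0.1, 5
        terms = [
            math.exp(-lam) * lam**k / math.factorial(k) for k in range(n, n + 60)
        ]
        expected = math.fsum(terms) / (1 - math.exp(-lam))
        assert abundance_p_value(n, lam) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(8.0e-7, rel=0.02)

    def test_large_lambda_limit(self):
        assert abundance_p_value(5, 1e4) == pytest.approx(1.0)

    def test_zero_lambda_with_excess_count(self):
        assert abundance_p_value(5, 0.0) == 0.0


class TestDenoiseSample:
    def test_identical_error_free_reads_one_asv(self, rng):
        seq = random_seq(rng, 120)
        reads = [Read(f"r{i}", seq, [35] * 120) for i in range(1000)]
        asvs = denoise_reads(reads)
        assert len(asvs) == 1
        assert asvs[0].sequence == seq and asvs[0].count == 1000

    def test_two_planted_variants_recovered(self):
        for seed in range(5):
            cfg = SimConfig(seed=100 + seed, n_variants=2, variant_divergence=5,
                            copy_weights=(0.5, 0.5), depth=1000, quality=30)
            reads, truth = simulate_genome_reads(cfg)
            asvs = denoise_reads(reads)
            assert len(asvs) == 2
            assert {a.sequence for a in asvs} == set(truth.true_variant_sequences)
            assert all(abs(a.count - 500) < 80 for a in asvs)

    def test_singletons_can_never_split(self, rng):
        """990 reads of a template plus 10 one-error singletons stay together."""
        center = random_seq(rng, 120)
        uniques = [_unique(center, 990, q=20)]
        seen = {center}
        while len(seen) < 11:
            v = mutate(np.random.default_rng(len(seen)), center, 1)
            if v not in seen:
                seen.add(v)
                uniques.append(_unique(v, 1, q=20))
        asvs = denoise_sample(uniques)
        assert len(asvs) == 1 and asvs[0].count == 1000

    def test_empty_input(self):
        assert denoise_sample([]) == []

    def test_asv_counts_conserve_reads(self):
        cfg = SimConfig(seed=42, n_variants=2, variant_divergence=3, depth=400)
        reads, _ = simulate_genome_reads(cfg)
        asvs = denoise_reads(reads)
        assert sum(a.count for a in asvs) == 400

    def test_stricter_omega_never_increases_asv_count(self):
        cfg = SimConfig(seed=17, n_variants=3, variant_divergence=4, depth=600,
                        quality=25)
        reads, _ = simulate_genome_reads(cfg)
        uniques = dereplicate_with_quality(reads)
        counts = [
            len(denoise_sample(uniques, cfg=DenoiseConfig(omega_a=om)))
            for om in (1e-10, 1e-40, 1e-80)
        ]
        assert counts == sorted(counts, reverse=True)


class TestLearnErrorModel:
    def test_error_free_input_hits_the_floor(self, rng):
        seq = random_seq(rng, 120)
        reads = [Read(f"r{i}", seq, [35] * 120) for i in range(200)]
        model = learn_error_model([dereplicate_with_quality(reads)])
        off = model.p[:, :, 35].copy()
        off[np.eye(4, dtype=bool)] = 0
        assert off.max() == pytest.approx(1e-7)

    def test_recovers_planted_substitution_rate(self):
        """1% substitutions at q30, depth >= 1e5 bases, recovered within 0.002."""
        cfg = SimConfig(seed=8, n_variants=1, depth=1000, quality=30,
                        error_rate_by_quality={30: 0.01})
        reads, _ = simulate_genome_reads(cfg)
        model = learn_error_model([dereplicate_with_quality(reads)])
        assert model.learned
        off = model.p[:, :, 30].copy()
        off[np.eye(4, dtype=bool)] = 0
        total = off.sum(axis=1).mean()
        assert abs(total - 0.01) <= 0.002


class TestBimeraRemoval:
    def test_constructed_bimera_removed(self, rng):
        a, b = random_seq(rng, 110), random_seq(rng, 110)
        child = a[:60] + b[60:]
        sample = [ASV(a, 100), ASV(b, 100), ASV(child, 10)]
        out = remove_bimeras_consensus([sample])
        assert [x.sequence for x in out[0]] == [a, b]

    def test_no_decomposition_retained(self, rng):
        a, b = random_seq(rng, 110), random_seq(rng, 110)
        other = random_seq(rng, 110)
        sample = [ASV(a, 100), ASV(b, 100), ASV(other, 10)]
        out = remove_bimeras_consensus([sample])
        assert len(out[0]) == 3

    def test_consensus_fraction_rule(self, rng):
        """Flagged in 1 of 2 testable samples (0.5 <= 0.9) -> retained."""
        a, b = random_seq(rng, 110), random_seq(rng, 110)
        child = a[:60] + b[60:]
        s1 = [ASV(a, 100), ASV(b, 100), ASV(child, 10)]
        unrelated = [ASV(random_seq(rng, 110), 200), ASV(random_seq(rng, 110), 150),
                     ASV(child, 10)]
        out = remove_bimeras_consensus([s1, unrelated])
        assert any(x.sequence == child for x in out[0])

    def test_underabundant_parents_do_not_flag(self, rng):
        a, b = random_seq(rng, 110), random_seq(rng, 110)
        child = a[:60] + b[60:]
        sample = [ASV(a, 15), ASV(b, 15), ASV(child, 10)]  # < 2x fold
        out = remove_bimeras_consensus([sample])
        assert len(out[0]) == 3


class TestDenoisePaired:
    def test_error_free_pairs_recover_template(self):
        cfg = SimConfig(seed=31, depth=300, v9_length=130,
                        error_rate_by_quality=NOERR)
        reads, truth = simulate_genome_reads(cfg)
        pairs = pairs_from_reads(reads, 80)
        asvs = denoise_paired(pairs)
        assert len(asvs) == 1
        assert asvs[0].sequence == truth.true_variant_sequences[0]
        assert asvs[0].count == 300

    def test_uncovered_middle_means_no_overlap_so_pairs_drop(self, rng):
        """Templates too long for the truncated mates to overlap yield no ASV.

        A middle stretch covered by neither mate implies the denoised mates
        cannot overlap by the required exact 12 nt, so such pairs are
        dropped rather than collapsed — the paired protocol simply cannot
        represent these templates.
        """
        a = random_seq(rng, 137)
        b = a[:65] + {"A": "C", "C": "G", "G": "T", "T": "A"}[a[65]] + a[66:]
        reads = [Read(f"a{i}", a, [35] * 137) for i in range(100)]
        reads += [Read(f"b{i}", b, [35] * 137) for i in range(100)]
        cfg = DenoiseConfig(trunc_len=60)
        assert denoise_paired(pairs_from_reads(reads, 60), cfg) == []

    def test_short_pairs_dropped(self, rng):
        from v9var.readprep import ReadPair

        short = Read("s", random_seq(rng, 50), [30] * 50)
        assert denoise_paired([ReadPair(short, short)]) == []
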