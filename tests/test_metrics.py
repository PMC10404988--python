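"""Per-genome profiles, environmental matching, protocol comparison, similarity."""

import numpy as np
import pandas as pd
import pytest

from v9var.cluster import SwarmConfig, env_prefilter
from v9var.extract import Barcode, dereplicate
from v9var.metrics import (
    LabeledUnit,
    compare_protocols,
    genome_profile,
    match_to_environment,
    protocol_summary,
    similarity_levels,
)
from v9var.readprep import Read
from v9var.simulate import (
    EnvCommunityConfig,
    SimConfig,
    pairs_from_reads,
    simulate_env_samples,
    simulate_genome_reads,
)

from conftest import mutate, random_seq

NOERR = {q: 0.0 for q in range(94)}


class TestGenomeProfile:
    def test_top_fraction_arithmetic(self):
        p = genome_profile("g", [Barcode("AAAA", 90), Barcode("CCCC", 10)])
        assert p.n_v9_reads == 100
        assert p.n_barcodes == 2
        assert p.top_barcode_fraction == 0.9

    def test_single_barcode(self):
        p = genome_profile("g", [Barcode("AAAA", 5)], swarms=[1], clusters97=[1], asvs=[1])
        assert p.top_barcode_fraction == 1.0
        assert p.n_swarms == p.n_otu97 == p.n_asvs == 1

    def test_missing_stage_reported_absent(self):
        p = genome_profile("g", [Barcode("AAAA", 5)])
        assert p.n_swarms is None and p.n_asvs is None

    def test_truth_consistency_for_two_variants(self):
        cfg = SimConfig(seed=5, n_variants=2, variant_divergence=3,
                        copy_weights=(0.8, 0.2), depth=500,
                        error_rate_by_quality=NOERR)
        reads, truth = simulate_genome_reads(cfg)
        bars = dereplicate([(r.bases, "g") for r in reads])
        p = genome_profile("g", bars)
        assert p.n_barcodes == 2
        assert p.top_barcode_fraction == pytest.approx(0.8, abs=0.06)


class TestMatchToEnvironment:
    def _env_table(self, seqs_counts):
        return pd.DataFrame(
            {f"s{i}": [c // 2, c - c // 2] for i, (s, c) in [(0, (None, 0))]}
        )

    def test_identical_barcode_found(self, rng):
        seq = random_seq(rng, 110)
        table = pd.DataFrame({"s1": [250], "s2": [250]}, index=[seq])
        recs = match_to_environment([Barcode(seq, 50)], table, source_id="g")
        assert len(recs) == 1
        assert recs[0].rank == "predominant"
        assert recs[0].found and recs[0].env_reads >= 500

    def test_distant_barcode_not_found(self, rng):
        src = random_seq(rng, 110)
        env = mutate(rng, src, 5)  # >= 3 edits away
        table = pd.DataFrame({"s1": [300], "s2": [300]}, index=[env])
        recs = match_to_environment(
            [Barcode(src, 50)], table, source_id="g",
            swarm_cfg=SwarmConfig(fastidious=False),
        )
        mine = [r for r in recs if r.rank == "predominant"]
        assert len(mine) == 1 and mine[0].env_reads == 0

    def test_dominant_only_environment_modal_outcome(self):
        """Predominant OTU found, minor intragenomic OTUs absent."""
        cfg = SimConfig(seed=13, n_variants=3, variant_divergence=4,
                        copy_weights=(0.8, 0.1, 0.1), depth=400,
                        error_rate_by_quality=NOERR)
        reads, truth = simulate_genome_reads(cfg)
        bars = dereplicate([(r.bases, "g") for r in reads])
        dom = truth.true_variant_sequences[0]
        table = pd.DataFrame({"s1": [400], "s2": [350]}, index=[dom])
        recs = match_to_environment(bars, table, source_id="g")
        assert sum(r.rank == "predominant" for r in recs) == 1
        for r in recs:
            assert r.found == (r.rank == "predominant")


class TestCompareProtocols:
    def test_error_free_single_variant_all_protocols_agree(self):
        cfg = SimConfig(seed=3, depth=200, v9_length=130,
                        error_rate_by_quality=NOERR)
        reads, _ = simulate_genome_reads(cfg)
        taxa = {"TaxonA": {"merged": reads, "pairs": pairs_from_reads(reads, 80)}}
        df = compare_protocols(taxa)
        assert df.loc["TaxonA"].tolist() == [1, 1, 1, 1, 1]

    def test_ratio_arithmetic(self):
        df = pd.DataFrame(
            {
                "swarm_on_barcodes": [3],
                "denoise_merged": [2],
                "denoise_paired": [2],
                "denoise_merged+swarm": [2],
                "denoise_paired+swarm": [2],
            },
            index=["t"],
        )
        s = protocol_summary(df)
        assert s["median_swarm_vs_denoised"] == 1.5

    def test_taxon_order_invariance(self):
        cfg = SimConfig(seed=4, depth=150)
        reads, _ = simulate_genome_reads(cfg)
        cfg2 = SimConfig(seed=5, depth=150)
        reads2, _ = simulate_genome_reads(cfg2)
        a = compare_protocols({"A": {"merged": reads}, "B": {"merged": reads2}})
        b = compare_protocols({"B": {"merged": reads2}, "A": {"merged": reads}})
        pd.testing.assert_frame_equal(a, b)


class TestSimilarityLevels:
    def _unit(self, rng, seq, source, species, genus, taxon):
        return LabeledUnit(source + "_u", seq, source, species, genus, taxon)

    def test_level_assignment_and_identical_conspecifics(self, rng):
        seq = random_seq(rng, 110)
        units = [
            self._unit(rng, seq, "g1", "sp1", "gen1", "tax1"),
            self._unit(rng, seq, "g2", "sp1", "gen1", "tax1"),
            self._unit(rng, mutate(rng, seq, 5), "g3", "sp2", "gen1", "tax1"),
            self._unit(rng, mutate(rng, seq, 30), "g4", "sp3", "gen2", "tax2"),
        ]
        recs = similarity_levels(units)
        by_pair = {(r.unit_a, r.unit_b): r for r in recs}
        conspecific = by_pair[("g1_u", "g2_u")]
        assert conspecific.level == "intra_species" and conspecific.pid == 1.0
        assert by_pair[("g1_u", "g3_u")].level == "inter_species"
        assert by_pair[("g1_u", "g4_u")].level == "inter_taxon"

    def test_intragenomic_most_specific(self, rng):
        seq = random_seq(rng, 110)
        units = [
            self._unit(rng, seq, "g1", "sp1", "gen1", "tax1"),
            self._unit(rng, mutate(rng, seq, 2), "g1", "sp1", "gen1", "tax1"),
        ]
        assert similarity_levels(units)[0].level == "intragenomic"

    def test_needs_two_units(self, rng):
        with pytest.raises(ValueError):
            similarity_levels([self._unit(rng, "ACGT", "g", "s", "ge", "t")])

    def test_overlapping_divergence_bands_detectable(self, rng):
        """Intragenomic vs inter-species identity distributions can overlap."""
        base = random_seq(rng, 110)
        units = [
            self._unit(rng, base, "g1", "sp1", "gen1", "tax1"),
            self._unit(rng, mutate(rng, base, 2), "g1", "sp1", "gen1", "tax1"),
            self._unit(rng, mutate(rng, base, 5), "g2", "sp2", "gen1", "tax1"),
        ]
        recs = similarity_levels(units)
        intra = [r.pid for r in recs if r.level == "intragenomic"]
        inter = [r.pid for r in recs if r.level == "inter_species"]
        assert intra and inter
        assert min(intra) > 0.9 and max(inter) > 0.9  # bands overlap
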