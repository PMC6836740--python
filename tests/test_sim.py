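"""Simulator contracts: determinism, calibration, and ground-truth invariants."""

import dataclasses
import math

import numpy as np
import pytest

from pollenphase import (
    ConfigError,
    SimConfig,
    simulate_all,
    simulate_bacs,
    simulate_diploid_genome,
    simulate_gametes,
    simulate_pollen_calls,
)


class TestDiploidGenome:
    def test_zero_het_rate_means_identical_haplotypes(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=5_000, het_rate=0.0,
            fragment_length_range=(1_000, 2_000), seed=1,
        )
        genome = simulate_diploid_genome(cfg)
        assert genome.n_snps() == 0
        assert genome.hap_a["chr1"] == genome.hap_b["chr1"]

    def test_snp_count_within_binomial_bounds(self):
        # E = L*p = 1020, sd = sqrt(L*p*(1-p)) ~ 31.8
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, het_rate=0.0102, seed=3)
        genome = simulate_diploid_genome(cfg)
        expected = 100_000 * 0.0102
        sd = math.sqrt(100_000 * 0.0102 * (1 - 0.0102))
        assert abs(genome.n_snps() - expected) < 3 * sd

    def test_haplotypes_differ_exactly_at_snp_sites(self, small_genome):
        for chrom in small_genome.chromosomes:
            a = np.frombuffer(small_genome.hap_a[chrom].encode(), dtype="S1")
            b = np.frombuffer(small_genome.hap_b[chrom].encode(), dtype="S1")
            diff = np.flatnonzero(a != b)
            table = small_genome.snp_table(chrom)
            assert np.array_equal(diff, table.positions)
            assert (table.allele_a != table.allele_b).all()

    def test_same_seed_is_byte_identical(self, small_config):
        g1 = simulate_diploid_genome(small_config)
        g2 = simulate_diploid_genome(small_config)
        assert g1.hap_a == g2.hap_a and g1.hap_b == g2.hap_b
        for chrom in g1.chromosomes:
            assert np.array_equal(
                g1.snp_table(chrom).positions, g2.snp_table(chrom).positions
            )

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(het_rate=1.2), "het_rate"),
            (dict(het_rate=-0.1), "het_rate"),
            (dict(n_cells=0), "n_cells"),
            (dict(coverage_range=(0.9, 0.5)), "coverage_range"),
            (dict(coverage_range=(0.0, 0.5)), "coverage_range"),
            (dict(co_rate=-1.0), "co_rate"),
            (dict(end_bias=0.0), "end_bias"),
            (dict(chrom_length=0), "chrom_length"),
            (dict(fragment_length_range=(0, 10)), "fragment_length_range"),
            (
                dict(chrom_length=5_000, fragment_length_range=(6_000, 7_000)),
                "fragment_length_range",
            ),
        ],
    )
    def test_invalid_config_names_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs)


class TestGametes:
    def test_no_recombination_gives_single_segments(self, small_genome, small_config):
        cfg = dataclasses.replace(small_config, co_rate=0.0)
        for gamete in simulate_gametes(small_genome, cfg):
            for chrom in small_genome.chromosomes:
                assert gamete.breakpoints[chrom].size == 0
                segs = gamete.segments(chrom, small_genome.chrom_length(chrom))
                assert len(segs) == 1

    def test_crossover_rate_calibrates_to_1_3_per_chromosome(self):
        # Monte Carlo over 10 seeds x 12 cells x 17 chromosomes
        total = 0
        n_pairs = 0
        for seed in range(10):
            cfg = SimConfig(
                n_chromosomes=17, chrom_length=5_000, het_rate=0.0, n_cells=12,
                co_rate=1.3, fragment_length_range=(1_000, 2_000), seed=seed,
            )
            genome = simulate_diploid_genome(cfg)
            for gamete in simulate_gametes(genome, cfg):
                for chrom in genome.chromosomes:
                    total += gamete.breakpoints[chrom].size
                    n_pairs += 1
        mean = total / n_pairs
        se = math.sqrt(1.3 / n_pairs)
        assert abs(mean - 1.3) < 4 * se

    def test_end_bias_concentrates_crossovers_at_chromosome_ends(self):
        # Beta(0.5, 0.5) puts ~59% of mass in the terminal 20% of each end
        cfg = SimConfig(
            n_chromosomes=17, chrom_length=10_000, het_rate=0.0, n_cells=12,
            co_rate=5.0, fragment_length_range=(1_000, 2_000), seed=5,
        )
        genome = simulate_diploid_genome(cfg)
        rel = []
        for gamete in simulate_gametes(genome, cfg):
            for chrom in genome.chromosomes:
                rel.extend(gamete.breakpoints[chrom] / 10_000)
        rel = np.array(rel)
        terminal = ((rel <= 0.2) | (rel >= 0.8)).mean()
        assert terminal > 0.45

    def test_segments_partition_chromosome_and_alternate(self, small_sim):
        genome, gametes, _, _ = small_sim
        for gamete in gametes:
            for chrom in genome.chromosomes:
                length = genome.chrom_length(chrom)
                segs = gamete.segments(chrom, length)
                assert segs[0][0] == 0 and segs[-1][1] == length
                for (s1, e1, h1), (s2, e2, h2) in zip(segs, segs[1:]):
                    assert e1 == s2 and h1 != h2
                bp = gamete.breakpoints[chrom]
                assert (np.diff(bp) > 0).all()
                assert bp.size == 0 or (0 < bp.min() and bp.max() < length)


class TestPollenCalls:
    def test_noise_free_calls_reproduce_gamete_alleles(self, noise_free_sim):
        genome, gametes, observations, _ = noise_free_sim
        for gamete, obs in zip(gametes, observations):
            for chrom in genome.chromosomes:
                table = genome.snp_table(chrom)
                src = gamete.source_at(chrom, table.positions)
                expected = np.where(src == "A", table.allele_a, table.allele_b)
                assert (obs.bases[chrom] == expected).all()
                assert not obs.error_flags[chrom].any()

    def test_fixed_coverage_calibrates_to_point_66(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=100_000, coverage_range=(0.66, 0.66), seed=9
        )
        genome, _, observations, _ = simulate_all(cfg)
        fractions = [obs.called_fraction() for obs in observations]
        n_sites = genome.n_snps()
        se_mean = math.sqrt(0.66 * 0.34 / n_sites) / math.sqrt(len(fractions))
        assert abs(np.mean(fractions) - 0.66) < 4 * se_mean

    def test_error_flags_within_binomial_bounds(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=1_000_000, het_rate=0.01, n_cells=1,
            coverage_range=(1.0, 1.0), genotype_error_rate=0.1, seed=13,
        )
        genome, gametes, observations, _ = (
            simulate_diploid_genome(cfg),
            None, None, None,
        )
        gametes = simulate_gametes(genome, cfg)
        observations = simulate_pollen_calls(genome, gametes, cfg)
        n_sites = genome.n_snps()
        n_err = observations[0].n_errors()
        sd = math.sqrt(n_sites * 0.1 * 0.9)
        assert abs(n_err - 0.1 * n_sites) < 4 * sd
        # flipped calls really carry the other allele
        chrom = "chr1"
        table = genome.snp_table(chrom)
        err = observations[0].error_flags[chrom]
        src = gametes[0].source_at(chrom, table.positions)
        other = np.where(src == "A", table.allele_b, table.allele_a)
        assert (observations[0].bases[chrom][err] == other[err]).all()

    def test_most_sites_seen_in_at_least_two_cells(self):
        # 12 cells at p = 0.66: 1 - (1-p)^12 - 12 p (1-p)^11 > 0.999
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=100_000, coverage_range=(0.66, 0.66), seed=21
        )
        genome, _, observations, _ = simulate_all(cfg)
        support = np.zeros(genome.n_snps())
        for obs in observations:
            support += (obs.bases["chr1"] != ".").astype(int)
        assert (support >= 2).mean() > 0.999


class TestBacs:
    def test_zero_fragments(self, small_genome, small_config):
        cfg = dataclasses.replace(small_config, n_fragments=0)
        assert simulate_bacs(small_genome, cfg) == []

    def test_sequences_copy_truth_haplotype(self, small_sim):
        genome, _, _, bacs = small_sim
        for b in bacs:
            source = genome.hap_a if b.truth_haplotype == "A" else genome.hap_b
            assert b.sequence == source[b.chromosome][b.start : b.end]
            assert 0 <= b.start < b.end <= genome.chrom_length(b.chromosome)

    def test_haplotype_ratio_near_50_50(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=50_000, het_rate=0.0, n_fragments=400,
            fragment_length_range=(1_000, 2_000), seed=17,
        )
        genome = simulate_diploid_genome(cfg)
        bacs = simulate_bacs(genome, cfg)
        n_a = sum(1 for b in bacs if b.truth_haplotype == "A")
        assert abs(n_a - 200) < 3 * math.sqrt(400 * 0.25)

    def test_simulate_all_is_deterministic(self, small_config):
        g1, ga1, o1, b1 = simulate_all(small_config)
        g2, ga2, o2, b2 = simulate_all(small_config)
        assert [b.sequence for b in b1] == [b.sequence for b in b2]
        assert all(
            np.array_equal(x.breakpoints[c], y.breakpoints[c])
            for x, y in zip(ga1, ga2)
            for c in g1.chromosomes
        )
        assert all(
            np.array_equal(x.bases[c], y.bases[c])
            for x, y in zip(o1, o2)
            for c in g1.chromosomes
        )
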