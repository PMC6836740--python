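"""Haplotype-family assignment by hamming-distance chaining."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pollenphase import (
    BacRecord,
    Barcode,
    BarcodeProfile,
    PhaseCall,
    PhaseParams,
    complement,
    evaluate_phasing,
    hamming,
    phase_chromosome,
    phase_genome,
    summarize_calls,
)
from pollenphase.anchor import AnchorAssignment
from pollenphase.phase import (
    HAP_A,
    HAP_B,
    REASON_AMBIGUOUS,
    REASON_SINGLE_CELL,
    REASON_TOO_FEW_SNPS,
    REASON_UNANCHORED,
    UNPHASED,
    complementarity_violations,
)

from _helpers import make_profile


def run(profiles, params=None):
    positions = {p.fragment_id: float(i) for i, p in enumerate(profiles)}
    calls, families = phase_chromosome(profiles, positions, params, chromosome="chr1")
    return {c.fragment_id: c for c in calls}, families


class TestPhaseChromosome:
    def test_two_complementary_clusters_partition_cleanly(self):
        code_a, code_b = "110100", "001011"
        profiles = [
            make_profile(f"f{i}", code_a if i % 2 == 0 else code_b) for i in range(10)
        ]
        calls, families = run(profiles)
        groups = {code_a: set(), code_b: set()}
        for i in range(10):
            assert calls[f"f{i}"].call in (HAP_A, HAP_B)
            groups[code_a if i % 2 == 0 else code_b].add(calls[f"f{i}"].call)
        assert groups[code_a] != groups[code_b]  # clean split up to label swap
        assert len(groups[code_a]) == len(groups[code_b]) == 1
        assert complementarity_violations(*families) == []

    def test_one_crossover_shifts_family_barcode_by_one_bit(self):
        # crossover in cell 0 between positions 2 and 3: brute-force check that
        # the greedy calls equal the unique 2-coloring consistent with truth
        before_a, after_a = "011", "111"
        profiles = []
        truth = {}
        for i in range(3):
            profiles.append(make_profile(f"a{i}", before_a))
            truth[f"a{i}"] = "A"
            profiles.append(make_profile(f"b{i}", str(complement(Barcode.from_string(before_a)))))
            truth[f"b{i}"] = "B"
        for i in range(3, 6):
            profiles.append(make_profile(f"a{i}", after_a))
            truth[f"a{i}"] = "A"
            profiles.append(make_profile(f"b{i}", str(complement(Barcode.from_string(after_a)))))
            truth[f"b{i}"] = "B"
        calls, families = run(profiles)
        for labeling in ({"A": HAP_A, "B": HAP_B}, {"A": HAP_B, "B": HAP_A}):
            if all(calls[f].call == labeling[t] for f, t in truth.items()):
                break
        else:
            pytest.fail("calls do not match truth under either labeling")
        fam_a, fam_b = families
        codes = [bc for _, bc in fam_a.barcode_track]
        distinct = {str(c) for c in codes}
        assert len(distinct) == 2
        first, second = sorted(distinct)
        assert hamming(Barcode.from_string(first), Barcode.from_string(second)) == 1

    def test_single_cell_support_is_unphased(self):
        profiles = [make_profile("f0", "110100"), make_profile("f1", "110100")]
        profiles.append(make_profile("lonely", "100000", observed="100000"))
        calls, _ = run(profiles)
        assert calls["lonely"].call == UNPHASED
        assert calls["lonely"].reason == REASON_SINGLE_CELL

    def test_too_few_snps_is_unphased(self):
        profiles = [make_profile("f0", "110100"), make_profile("thin", "110100", n_snps=2)]
        calls, _ = run(profiles)
        assert calls["thin"].call == UNPHASED
        assert calls["thin"].reason == REASON_TOO_FEW_SNPS

    def test_equidistant_fragment_is_ambiguous(self):
        calls, _ = run([make_profile("seed", "1100"), make_profile("mid", "1010")])
        assert calls["mid"].call == UNPHASED
        assert calls["mid"].reason == REASON_AMBIGUOUS

    def test_assigned_calls_respect_min_margin(self):
        profiles = [make_profile(f"f{i}", "110100") for i in range(6)]
        params = PhaseParams(min_margin=2)
        calls, _ = run(profiles, params)
        for c in calls.values():
            if c.call != UNPHASED:
                assert c.margin >= 2

    def test_empty_input(self):
        calls, families = phase_chromosome([], {}, chromosome="chr1")
        assert calls == [] and families[0].members == []


class TestPhaseGenome:
    def test_unanchored_and_missing_profiles_reported(self):
        profiles = {f"f{i}": make_profile(f"f{i}", "110100") for i in range(4)}
        anchors = [
            AnchorAssignment(f"f{i}", "chr1", 1.0, 0.0, float(i)) for i in range(4)
        ]
        anchors.append(AnchorAssignment("lost", None, 0.2, 0.1, None, "below_min_coverage"))
        anchors.append(AnchorAssignment("bare", "chr1", 0.9, 0.0, 9.0))
        calls, summary, _families = phase_genome(anchors, profiles)
        by_id = {c.fragment_id: c for c in calls}
        assert by_id["lost"].reason == REASON_UNANCHORED
        assert by_id["bare"].reason == REASON_TOO_FEW_SNPS
        assert summary.n_total == 6
        assert summary.n_phased + summary.n_unphased == summary.n_total

    def test_zero_fragments_summary(self):
        calls, summary, _ = phase_genome([], {})
        assert summary.n_total == 0 and summary.phased_fraction == 0.0

    @given(
        st.lists(st.sampled_from([HAP_A, HAP_B, UNPHASED]), min_size=0, max_size=50)
    )
    def test_summary_counts_always_partition(self, outcomes):
        calls = [
            PhaseCall(f"f{i}", "chr1", o, reason=None if o != UNPHASED else "x")
            for i, o in enumerate(outcomes)
        ]
        s = summarize_calls(calls)
        assert s.n_phased_a + s.n_phased_b + s.n_unphased == s.n_total == len(outcomes)


class TestEvaluation:
    def _truth(self, haps):
        return [
            BacRecord(
                id=f"f{i}", sequence="", chromosome="chr1", start=i * 10,
                end=i * 10 + 5, truth_haplotype=h,
            )
            for i, h in enumerate(haps)
        ]

    def test_perfect_calls(self):
        truth = self._truth(["A", "B"] * 5)
        calls = [PhaseCall(b.id, "chr1", b.truth_haplotype) for b in truth]
        ev = evaluate_phasing(calls, truth)
        assert ev.accuracy == 1.0 and ev.switch_errors == 0 and ev.unphased_rate == 0.0

    def test_global_flip_is_not_an_error(self):
        truth = self._truth(["A", "B"] * 5)
        flip = {"A": HAP_B, "B": HAP_A}
        calls = [PhaseCall(b.id, "chr1", flip[b.truth_haplotype]) for b in truth]
        ev = evaluate_phasing(calls, truth)
        assert ev.accuracy == 1.0 and ev.switch_errors == 0

    def test_one_misassignment_among_100_gives_two_switch_errors(self):
        truth = self._truth(["A"] * 100)
        calls = [PhaseCall(b.id, "chr1", "A") for b in truth]
        calls[50] = PhaseCall("f50", "chr1", "B")
        ev = evaluate_phasing(calls, truth)
        assert ev.accuracy == pytest.approx(0.99)
        assert ev.switch_errors == 2

    def test_label_swap_invariance(self, rng):
        haps = list(rng.choice(["A", "B"], size=40))
        truth = self._truth(haps)
        flip = {"A": HAP_B, "B": HAP_A}
        calls = [
            PhaseCall(b.id, "chr1", b.truth_haplotype if i % 7 else flip[b.truth_haplotype])
            for i, b in enumerate(truth)
        ]
        swapped = [PhaseCall(c.fragment_id, c.chromosome, flip[c.call]) for c in calls]
        e1, e2 = evaluate_phasing(calls, truth), evaluate_phasing(swapped, truth)
        assert e1.accuracy == e2.accuracy
        assert e1.switch_errors == e2.switch_errors


class TestEndToEnd:
    def test_noise_free_small_sim_is_perfectly_phased(self, noise_free_sim):
        from pollenphase import build_profile
        from pollenphase.anchor import anchor_fragments, build_kmer_index

        genome, gametes, observations, bacs = noise_free_sim
        reference = {}
        for chrom in genome.chromosomes:
            reference[f"{chrom}_A"] = genome.hap_a[chrom]
            reference[f"{chrom}_B"] = genome.hap_b[chrom]
        index = build_kmer_index(reference, chrom_of=lambda n: n.rsplit("_", 1)[0])
        anchors = anchor_fragments(bacs, index)
        bac_by_id = {b.id: b for b in bacs}
        profiles = {
            a.fragment_id: build_profile(
                bac_by_id[a.fragment_id],
                genome.snp_table(a.chromosome),
                observations,
            )
            for a in anchors
            if a.chromosome is not None
        }
        calls, summary, families = phase_genome(anchors, profiles)
        ev = evaluate_phasing(calls, bacs)
        assert ev.accuracy == 1.0
        assert ev.unphased_rate == 0.0
        assert ev.switch_errors == 0
        # family barcodes are complementary everywhere except transiently
        # around a genuine crossover of the offending cell
        window = 5
        for chrom, (fam_a, fam_b) in families.items():
            members = sorted(p for p, _ in fam_a.members + fam_b.members)
            for pos, cell in complementarity_violations(fam_a, fam_b):
                i = members.index(pos)
                lo = members[max(i - 2 * window, 0)]
                hi = members[min(i + 2 * window, len(members) - 1)]
                bps = gametes[cell].breakpoints[chrom]
                assert ((bps >= lo) & (bps <= hi)).any(), (
                    f"violation at {pos} bit {cell} not near any crossover"
                )
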