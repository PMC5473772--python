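"""Operator-array design, hierarchical assembly, and the reporter split."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bifcros.arrays import (
    MVENUS_SPLIT,
    OL1_LAMBDA,
    SYNTHETIC_VENUS_LIKE,
    UAS_GAL4,
    AssemblyDesignError,
    OperatorMotif,
    OverhangMismatchError,
    ReporterSplitSpec,
    assemble_to_target,
    count_motifs,
    initial_state,
    make_building_block,
    reverse_complement,
    simulate_assembly_cycle,
    split_reporter,
)


def naive_motif_count(sequence: str, motif: str) -> int:
    """Brute-force sliding-window scan, both strands, interval-deduplicated."""
    hits = set()
    for pattern in (motif, reverse_complement(motif)):
        i = 0
        while i + len(pattern) <= len(sequence):
            if sequence[i : i + len(pattern)] == pattern:
                hits.add((i, i + len(pattern)))
                i += len(pattern)
            else:
                i += 1
    return len(hits)


class TestBuildingBlock:
    def test_same_seed_reproduces_block(self):
        a = make_building_block(seed=7)
        b = make_building_block(seed=7)
        assert a.core == b.core

    def test_different_seeds_differ_in_spacers(self):
        a = make_building_block(seed=7)
        b = make_building_block(seed=8)
        assert a.spacers != b.spacers

    def test_junction_reconstitutes_full_ol1(self, block):
        assert block.right_half_site + block.left_half_site == OL1_LAMBDA.sequence

    def test_no_enzyme_sites_inside_block(self, block):
        doubled = block.core + block.core  # catches sites spanning junctions
        for site in block.enzyme_sites:
            assert site not in doubled
            assert reverse_complement(site) not in doubled

    def test_spacers_carry_fixed_dinucleotide(self, block):
        assert block.spacers[0].startswith("CT")
        assert block.spacers[1].startswith("AG")

    def test_unavoidable_enzyme_site_raises(self):
        bad_uas = OperatorMotif("UAS", "CGGAAGACCG")  # contains BpiI site
        with pytest.raises(AssemblyDesignError):
            make_building_block(uas=bad_uas, seed=0)


class TestAssembly:
    def test_one_plus_one_gives_two_units_one_internal_ol1(self, block):
        s1 = initial_state(block)
        s2 = simulate_assembly_cycle(s1, s1)
        assert s2.unit_count == 2
        assert s2.step_index == 2
        assert count_motifs(s2, OL1_LAMBDA) == 1  # raw product: n-1 internal sites

    def test_32_plus_32_gives_64(self, block):
        s = initial_state(block)
        for _ in range(5):
            s = simulate_assembly_cycle(s, s)
        assert s.unit_count == 32
        s64 = simulate_assembly_cycle(s, s)
        assert s64.unit_count == 64

    def test_two_plus_two_sequence_equals_string_concatenation(self, block):
        s1 = initial_state(block)
        s2 = simulate_assembly_cycle(s1, s1)
        s4 = simulate_assembly_cycle(s2, s2)
        assert s4.sequence == block.core * 4

    def test_overhang_mismatch_raises(self, block):
        import dataclasses

        s1 = initial_state(block)
        bad = dataclasses.replace(s1, left_overhang="AAAA")
        with pytest.raises(OverhangMismatchError):
            simulate_assembly_cycle(s1, bad)

    @pytest.mark.parametrize(
        "target,steps", [(1, 1), (2, 2), (8, 4), (64, 7), (256, 9)]
    )
    def test_doubling_law_steps(self, block, target, steps):
        array = assemble_to_target(block, target)
        assert array.assembly_steps == steps
        assert array.n_units == target

    @pytest.mark.parametrize("target", [3, 6, 10, 63, 0])
    def test_non_power_of_two_rejected(self, block, target):
        with pytest.raises(ValueError, match="power"):
            assemble_to_target(block, target)

    @pytest.mark.parametrize("target", [1, 2, 8, 64])
    def test_motif_conservation_in_finalized_array(self, block, target):
        array = assemble_to_target(block, target)
        assert array.n_ol1 == target
        assert array.n_uas == target
        # independent brute-force scan
        assert naive_motif_count(array.sequence, OL1_LAMBDA.sequence) == target
        assert naive_motif_count(array.sequence, UAS_GAL4.sequence) == target

    def test_raw_product_has_n_minus_1_internal_ol1(self, block):
        s = initial_state(block)
        for _ in range(3):
            s = simulate_assembly_cycle(s, s)
        assert s.unit_count == 8
        assert count_motifs(s, OL1_LAMBDA) == 7

    def test_determinism_byte_identical_arrays(self):
        a = assemble_to_target(make_building_block(seed=3), 16)
        b = assemble_to_target(make_building_block(seed=3), 16)
        assert a.sequence == b.sequence

    def test_sequence_length_accounting(self, block):
        array = assemble_to_target(block, 8)
        flank = len(OL1_LAMBDA.right_half)
        assert len(array.sequence) == 8 * block.unit_length + flank


class TestCountMotifs:
    def test_matches_naive_scan_on_array(self, block):
        array = assemble_to_target(block, 32)
        assert count_motifs(array, OL1_LAMBDA) == naive_motif_count(
            array.sequence, OL1_LAMBDA.sequence
        )

    def test_counts_reverse_strand_occurrences(self):
        seq = "AAA" + reverse_complement(UAS_GAL4.sequence) + "TTT"
        assert count_motifs(seq, UAS_GAL4) == 1

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            count_motifs("ACGTN", OL1_LAMBDA)


class TestReporterSplit:
    def test_fragment_lengths(self):
        n_frag, c_frag = split_reporter(MVENUS_SPLIT)
        assert len(n_frag) == 154
        assert len(c_frag) == 238 - 154 == 84

    def test_mutation_applied_to_n_fragment(self):
        n_frag, _ = split_reporter(MVENUS_SPLIT)
        assert n_frag[151] == "L"
        assert SYNTHETIC_VENUS_LIKE[151] == "I"

    def test_partition_identity_with_mutation_reverted(self):
        n_frag, c_frag = split_reporter(MVENUS_SPLIT)
        restored = n_frag[:151] + "I" + n_frag[152:] + c_frag
        assert restored == SYNTHETIC_VENUS_LIKE

    def test_wrong_length_sequence_rejected(self):
        with pytest.raises(ValueError, match="length"):
            split_reporter(MVENUS_SPLIT, "MKV")

    def test_mismatched_mutation_residue_rejected(self):
        spec = ReporterSplitSpec(mutations=((152, "W", "L"),))
        with pytest.raises(ValueError, match="152"):
            split_reporter(spec, SYNTHETIC_VENUS_LIKE)

    def test_out_of_range_split_rejected(self):
        with pytest.raises(ValueError):
            ReporterSplitSpec(full_length=238, split_after=238)


@given(st.integers(min_value=0, max_value=8))
def test_doubling_law_property(k):
    """After k post-initial cycles the unit count is 2^k and steps are k+1."""
    block = make_building_block(seed=1)
    s = initial_state(block)
    for _ in range(k):
        s = simulate_assembly_cycle(s, s)
    assert s.unit_count == 2**k
    assert s.step_index == k + 1
    assert math.log2(s.unit_count) == s.step_index - 1
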