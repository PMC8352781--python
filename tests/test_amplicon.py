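import math

import numpy as np
import pytest

from beditscan.amplicon import (
    AmpliconDesign,
    align_read_to_amplicon,
    max_protospacer_conversion,
    quantify_editing,
    summarize_groups,
)
from beditscan.signature import reverse_complement
from beditscan.synthetic import simulate_amplicon_reads


@pytest.fixture
def minus_design():
    """Protospacer on the amplicon minus strand: CCT (revcomp of AGG PAM)
    immediately 5' of the reverse-complemented protospacer on the plus strand."""
    protospacer = "CGTCAGCATGCTAGCTGTCT"  # protospacer-strand sequence, A at pos 5
    left = "ACGT" * 8  # 32 bp
    right = "TGCA" * 8  # 32 bp
    amplicon = left + "CCT" + reverse_complement(protospacer) + right
    return AmpliconDesign(
        name="minus_toy",
        amplicon_sequence=amplicon,
        protospacer_start=36,
        protospacer_end=55,
        strand="-",
        target_adenine_position=5,
    )


class TestDesign:
    def test_pam_adjacency_plus_strand(self, design):
        assert design.pam_interval == (81, 83)
        assert design.amplicon_sequence[80:83] == "AGG"

    def test_pam_adjacency_minus_strand(self, minus_design):
        assert minus_design.pam_interval == (33, 35)

    def test_position_mapping_minus_strand(self, minus_design):
        # protospacer position 5 counts from the PAM-distal 5' end, which sits
        # at the plus-strand right edge for a minus-strand protospacer
        pos = minus_design.protospacer_to_amplicon(5)
        assert pos == 51
        assert minus_design.protospacer_base(5) == "A"
        assert minus_design.amplicon_sequence[pos - 1] == "T"

    def test_invalid_protospacer_length_rejected(self, design):
        with pytest.raises(ValueError):
            AmpliconDesign("bad", design.amplicon_sequence, 61, 79)


class TestAlignment:
    def test_identical_read_gap_free(self, design):
        aligned = align_read_to_amplicon(design.amplicon_sequence, design)
        assert not aligned.unalignable
        assert aligned.identity == 1.0
        assert not aligned.has_indel
        assert aligned.span == (1, len(design.amplicon_sequence))

    def test_three_bp_deletion_detected(self, design):
        seq = design.amplicon_sequence
        read = seq[:64] + seq[67:]  # remove 3 bp inside the protospacer
        aligned = align_read_to_amplicon(read, design)
        deleted = sorted(aligned.deletions)
        # one contiguous 3-bp gap inside the protospacer (placement may shift
        # within the repeat-equivalent stretch)
        assert len(deleted) == 3
        assert deleted[2] - deleted[0] == 2
        assert design.protospacer_start <= deleted[0] <= design.protospacer_end
        assert aligned.contains_indel_in_window

    def test_insertion_detected(self, design):
        seq = design.amplicon_sequence
        read = seq[:70] + "TTTT" + seq[70:]
        aligned = align_read_to_amplicon(read, design)
        assert aligned.insertions == ((70, 4),)
        assert aligned.contains_indel_in_window

    def test_reverse_complement_read_aligns_identically(self, design):
        seq = design.amplicon_sequence
        edited = seq[:64] + "G" + seq[65:]  # target position 65 edited
        fwd = align_read_to_amplicon(edited, design)
        rev = align_read_to_amplicon(reverse_complement(edited), design)
        assert fwd.base_at == rev.base_at
        assert fwd.deletions == rev.deletions

    def test_garbage_read_flagged_unalignable(self, design):
        aligned = align_read_to_amplicon("GC" * 70, design, min_identity=0.6)
        assert aligned.unalignable

    def test_empty_read_rejected(self, design):
        with pytest.raises(ValueError):
            align_read_to_amplicon("", design)


class TestQuantification:
    def test_all_reference_reads_give_zero_editing(self, design):
        aligned = [align_read_to_amplicon(design.amplicon_sequence, design, f"r{i}")
                   for i in range(20)]
        summary = quantify_editing(aligned, design)
        assert summary.indel_percent == 0.0
        assert all(v == 0.0 for v in summary.a_to_g_percent.values())
        assert summary.target_a_to_g_percent == 0.0

    def test_deletion_read_fraction_counted(self, design):
        seq = design.amplicon_sequence
        deleted = seq[:64] + seq[67:]
        reads = [seq] * 995 + [deleted] * 5
        aligned = [align_read_to_amplicon(r, design, f"r{i}") for i, r in enumerate(reads)]
        summary = quantify_editing(aligned, design)
        assert summary.indel_percent == pytest.approx(0.5)

    def test_indel_reads_excluded_from_substitution_denominator(self, design):
        seq = design.amplicon_sequence
        target = design.protospacer_to_amplicon(design.target_adenine_position)
        edited = seq[:target - 1] + "G" + seq[target:]
        deleted = seq[:64] + seq[67:]
        # 5 edited + 5 deleted: target % must be 5/5 edited out of 10-5=5 indel-free
        aligned = [align_read_to_amplicon(r, design, f"r{i}")
                   for i, r in enumerate([edited] * 5 + [deleted] * 5)]
        summary = quantify_editing(aligned, design)
        assert summary.target_a_to_g_percent == pytest.approx(100.0)
        assert summary.indel_percent == pytest.approx(50.0)

    def test_noise_free_simulation_recovered_exactly(self, design):
        # with no indels and no sequencing error the quantifier must reproduce
        # the realized per-position conversion fraction exactly
        n = 3000
        target = design.protospacer_to_amplicon(design.target_adenine_position)
        bystander = design.protospacer_to_amplicon(design.bystander_positions[0])
        reads = simulate_amplicon_reads(
            design, {target: 0.6, bystander: 0.3}, indel_rate=0.0, error_rate=0.0,
            n_reads=n, seed=21)
        aligned = [align_read_to_amplicon(r.sequence, design, r.name) for r in reads]
        summary = quantify_editing(aligned, design)
        for pos, rate in ((target, 0.6), (bystander, 0.3)):
            realized = sum(1 for r in reads if r.sequence[pos - 1] == "G") / n
            assert summary.a_to_g_percent[pos] == pytest.approx(realized * 100)
            # and the realized draw itself is binomial around the plan rate
            assert abs(realized - rate) <= 4 * math.sqrt(rate * (1 - rate) / n)

    def test_denominator_consistency(self, design):
        reads = simulate_amplicon_reads(
            design, {design.protospacer_to_amplicon(5): 0.5}, 0.05, 0.01,
            n_reads=300, seed=4)
        aligned = [align_read_to_amplicon(r.sequence, design, r.name) for r in reads]
        summary = quantify_editing(aligned, design)
        for pos, counts in summary.base_counts.items():
            assert sum(counts.values()) <= summary.n_spanning

    def test_no_spanning_reads_rejected(self, design):
        short = align_read_to_amplicon(design.amplicon_sequence[:30], design)
        with pytest.raises(ValueError):
            quantify_editing([short], design)


class TestMaxProtospacerConversion:
    def test_picks_highest_adenine(self, design):
        target = design.protospacer_to_amplicon(5)
        bystander = design.protospacer_to_amplicon(8)
        reads = simulate_amplicon_reads(
            design, {target: 0.5, bystander: 0.2}, 0.0, 0.0, n_reads=400, seed=8)
        aligned = [align_read_to_amplicon(r.sequence, design, r.name) for r in reads]
        summary = quantify_editing(aligned, design)
        best = max_protospacer_conversion(summary, design)
        assert best == pytest.approx(summary.a_to_g_percent[target])

    def test_all_zero_gives_zero(self, design):
        aligned = [align_read_to_amplicon(design.amplicon_sequence, design, f"r{i}")
                   for i in range(10)]
        summary = quantify_editing(aligned, design)
        assert max_protospacer_conversion(summary, design) == 0.0

    def test_minus_strand_uses_t_to_c_on_plus(self, minus_design):
        target = minus_design.protospacer_to_amplicon(5)
        reads = simulate_amplicon_reads(
            minus_design, {target: 0.4}, 0.0, 0.0, n_reads=1000, seed=13)
        aligned = [align_read_to_amplicon(r.sequence, minus_design, r.name)
                   for r in reads]
        summary = quantify_editing(aligned, minus_design)
        best = max_protospacer_conversion(summary, minus_design)
        assert abs(best - 40.0) <= 3 * math.sqrt(0.4 * 0.6 / 1000) * 100
        # the plus-strand position carries C (not G) in edited reads
        assert summary.base_counts[target].get("C", 0) > 0


class TestGroupSummaries:
    def _summary(self, target, indel=0.0):
        from beditscan.amplicon import EditingSummary
        return EditingSummary(
            sample="s", n_reads_total=100, n_spanning=100, n_reads_with_indel=0,
            base_counts={}, n_indel_free_spanning={}, a_to_g_percent={},
            indel_percent=indel, target_a_to_g_percent=target)

    def test_identical_samples_zero_sd(self):
        stats = summarize_groups({"g": [self._summary(60.0)] * 3})
        assert stats[0].mean_target_percent == 60.0
        assert stats[0].sd_target_percent == 0.0

    def test_two_sample_sd(self):
        stats = summarize_groups({"g": [self._summary(50.0), self._summary(70.0)]})
        assert stats[0].mean_target_percent == 60.0
        assert stats[0].sd_target_percent == pytest.approx(math.sqrt(200))

    def test_single_sample_sd_flagged_unavailable(self):
        stats = summarize_groups({"g": [self._summary(42.0)]})
        assert stats[0].mean_target_percent == 42.0
        assert stats[0].sd_target_percent is None

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups({"g": []})
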