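"""Consensus building, purity metrics, interruption cross-validation."""

import numpy as np
import pytest

from gaatract import (
    ConsensusTract,
    build_consensus,
    count_repeats,
    detect_interruptions,
    find_interruption_candidates,
    purity_metrics,
    select_window_reads,
)
from gaatract.repeatcall import RepeatCall
from gaatract.simulate import ReadRecord, mutate_sequence


def call_of(count, read_id="r", strand="+", identity=1.0):
    return RepeatCall(read_id, strand, tract_span=(0, 3 * count),
                      repeat_count=count, anchor_identity=identity)


class TestWindowSelection:
    def test_boundary_is_inclusive_at_20_units(self):
        calls = [call_of(c, f"r{c}") for c in (236, 237, 277, 278)]
        kept = select_window_reads(calls, 257, window=20)
        assert sorted(c.repeat_count for c in kept["+"]) == [237, 277]

    def test_empty_input_gives_empty_partitions(self):
        assert select_window_reads([], 100) == {"+": [], "-": []}

    def test_window_zero_keeps_exact_counts_only(self):
        calls = [call_of(c, f"r{c}") for c in (99, 100, 101)]
        kept = select_window_reads(calls, 100, window=0)
        assert [c.repeat_count for c in kept["+"]] == [100]

    def test_failed_reads_never_selected(self):
        kept = select_window_reads([RepeatCall("x", "fail")], 100)
        assert kept == {"+": [], "-": []}


def pairs_from_reads(design, sequences, strand="+"):
    out = []
    for i, seq in enumerate(sequences):
        read = ReadRecord(f"read{i:03d}", seq)
        call = count_repeats(read.id, read.sequence, design)
        out.append((call, read))
    return out


class TestBuildConsensus:
    def test_identical_clean_reads_give_pure_tract(self, design):
        pairs = pairs_from_reads(design, [design.template(100)] * 10)
        tract = build_consensus(pairs, design, "+", 100)
        assert tract.consensus_sequence == "GAA" * 100
        assert tract.n_reads == 10

    def test_substitution_errors_vote_out(self, design):
        """30 reads with independent 2% substitutions majority-vote back to
        the pure tract (oracle: per-column majority over the raw tracts,
        which all share one length because only substitutions occur)."""
        rng = np.random.default_rng(17)
        template = design.template(100)
        seqs = [mutate_sequence(template, (0.02, 0, 0), rng) for _ in range(30)]
        pairs = pairs_from_reads(design, seqs)
        tract = build_consensus(pairs, design, "+", 100)
        assert tract.consensus_sequence == "GAA" * 100

    def test_single_read_consensus_is_its_own_tract(self, design):
        pairs = pairs_from_reads(design, [design.template(50)])
        tract = build_consensus(pairs, design, "+", 50)
        assert tract.consensus_sequence == "GAA" * 50
        assert tract.n_reads == 1

    def test_no_reads_on_strand_returns_none(self, design):
        pairs = pairs_from_reads(design, [design.template(50)])
        assert build_consensus(pairs, design, "-", 50) is None

    def test_minus_strand_consensus_reported_in_sense_orientation(self, design):
        from gaatract.design import revcomp

        seqs = [revcomp(design.template(60)) for _ in range(5)]
        pairs = pairs_from_reads(design, seqs)
        tract = build_consensus(pairs, design, "-", 60)
        assert tract.consensus_sequence == "GAA" * 60


class TestPurityMetrics:
    def test_pure_tract_is_fully_matched(self, design):
        tract = ConsensusTract("s", 1, "+", "GAA" * 100, 10)
        report = purity_metrics(tract, design)
        assert report.percent_matches == 100
        assert report.percent_indels == 0
        assert report.copy_number == 100.0
        assert report.interruptions == ()

    def test_nine_scattered_deletions_give_three_percent_indels(self, design):
        rng = np.random.default_rng(4)
        seq = list("GAA" * 100)
        for pos in rng.choice(300, size=9, replace=False):
            seq[pos] = ""
        report = purity_metrics(ConsensusTract("s", 1, "+", "".join(seq), 10), design)
        assert report.percent_indels == 3

    def test_interrupted_tract_reports_candidate_and_reduced_matches(self, design):
        # GGAGAA differs from the pure frame by a single base, so the tract
        # must be short for that column to survive integer rounding
        seq = "GAA" * 20 + "GGAGAA" + "GAA" * 10
        report = purity_metrics(ConsensusTract("s", 1, "+", seq, 10), design)
        assert report.percent_matches < 100
        assert any(c.motif == "GGAGAA" for c in report.interruptions)

    def test_long_near_pure_tract_rounds_to_fully_matched(self, design):
        # 3 disrupted columns in 756 vanish at the integer precision the
        # report uses, mirroring how near-pure alleles print as 100/0
        seq = "GAA" * 50 + "GGAGAA" + "GAA" * 200
        report = purity_metrics(ConsensusTract("s", 1, "+", seq, 10), design)
        assert report.percent_matches == 100
        assert report.percent_indels == 0
        assert any(c.motif == "GGAGAA" for c in report.interruptions)


class TestInterruptions:
    def test_spliced_motif_round_trips_with_exact_spelling(self, design):
        seq = "GAA" * 100 + "GGAGAA" + "GAA" * 150
        plus = ConsensusTract("s", 1, "+", seq, 20)
        minus = ConsensusTract("s", 1, "-", seq, 20)
        calls = detect_interruptions(plus, minus, design)
        validated = [c for c in calls if c.validated]
        assert len(validated) == 1
        assert validated[0].motif == "GGAGAA"
        assert abs(validated[0].unit_offset - 100) <= 5

    def test_pure_tracts_yield_no_calls(self, design):
        plus = ConsensusTract("s", 1, "+", "GAA" * 200, 20)
        minus = ConsensusTract("s", 1, "-", "GAA" * 200, 20)
        assert detect_interruptions(plus, minus, design) == []

    def test_single_strand_candidate_stays_unvalidated(self, design):
        interrupted = ConsensusTract("s", 1, "+", "GAA" * 50 + "GGAGAA" + "GAA" * 50, 20)
        pure = ConsensusTract("s", 1, "-", "GAA" * 100, 20)
        calls = detect_interruptions(interrupted, pure, design)
        assert len(calls) == 1
        assert not calls[0].validated
        assert calls[0].strands == ("+",)

    def test_missing_strand_reports_candidates_unvalidated(self, design):
        interrupted = ConsensusTract("s", 1, "+", "GAA" * 50 + "GGAGAA" + "GAA" * 50, 20)
        calls = detect_interruptions(interrupted, None, design)
        assert calls and not any(c.validated for c in calls)

    def test_validated_set_symmetric_under_strand_swap(self, design):
        seq_p = "GAA" * 99 + "GGAGAA" + "GAA" * 151
        seq_m = "GAA" * 101 + "GGAGAA" + "GAA" * 149
        plus = ConsensusTract("s", 1, "+", seq_p, 20)
        minus = ConsensusTract("s", 1, "-", seq_m, 20)
        a = [c for c in detect_interruptions(plus, minus, design) if c.validated]
        b = [
            (c.unit_offset, c.motif)
            for c in detect_interruptions(minus, plus, design)
            if c.validated
        ]
        assert [(c.unit_offset, c.motif) for c in a] == b

    def test_offsets_beyond_tolerance_do_not_validate(self, design):
        plus = ConsensusTract("s", 1, "+", "GAA" * 100 + "GGAGAA" + "GAA" * 100, 20)
        minus = ConsensusTract("s", 1, "-", "GAA" * 120 + "GGAGAA" + "GAA" * 80, 20)
        calls = detect_interruptions(plus, minus, design, offset_tolerance=5)
        assert not any(c.validated for c in calls)

    def test_phase_compatible_gaps_are_length_noise_not_motifs(self, design):
        # an extra AA is an in-phase indel remnant: flagged, never validated
        seq = "GAA" * 100 + "AA" + "GAA" * 100
        cands = find_interruption_candidates(seq, "GAA")
        assert len(cands) == 1 and not cands[0].phase_break
        plus = ConsensusTract("s", 1, "+", seq, 20)
        minus = ConsensusTract("s", 1, "-", seq, 20)
        assert detect_interruptions(plus, minus, design) == []
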