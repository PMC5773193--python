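"""Alignment, event calling, per-target classification and quantification."""

import numpy as np
import pytest

from f0mosaic import (
    Amplicon,
    MutationEvent,
    ReadRecord,
    align_read,
    classify_events,
    classify_read,
    quantify_animal,
    read_fastq,
    write_fastq_gz,
)
from f0mosaic.simulate import (
    Allele,
    AllelePool,
    SimulationConfig,
    simulate_reads,
)

from conftest import delete, insert, rand_seq, substitute

FULL = lambda amp: (0, len(amp))  # noqa: E731


class TestAlignRead:
    def test_identical_read_has_no_events(self, coding_amplicon):
        events, span, identity = align_read(coding_amplicon.sequence, coding_amplicon)
        assert events == []
        assert span == (0, len(coding_amplicon))
        assert identity == 1.0

    def test_two_nt_deletion_called_at_leftmost_equivalent_position(
        self, coding_amplicon
    ):
        """Independent oracle: enumerate every 2-nt deletion of the
        reference that reproduces the read; the caller must report the
        leftmost one."""
        ref = coding_amplicon.sequence
        read = delete(ref, 25, 2)
        events, _, _ = align_read(read, coding_amplicon)
        assert len(events) == 1
        ev = events[0]
        assert (ev.kind, ev.length) == ("deletion", 2)
        equivalent = [
            s for s in range(len(ref) - 1) if delete(ref, s, 2) == read
        ]
        assert ev.ref_start == min(equivalent)

    def test_homopolymer_deletion_left_aligned(self):
        rng = np.random.default_rng(17)
        seq = rand_seq(rng, 100)
        seq[40:45] = list("AAAAA")
        seq[39], seq[45] = "C", "C"  # bound the homopolymer
        amp = Amplicon("a", "".join(seq), ())
        read = delete(amp.sequence, 43, 1)  # delete inside the run
        events, _, _ = align_read(read, amp)
        assert events == [MutationEvent("deletion", 40, 1)]

    def test_insertion_run_called_as_single_event(self, coding_amplicon):
        read = insert(coding_amplicon.sequence, 57, "TTT")
        events, _, _ = align_read(read, coding_amplicon)
        ins = [e for e in events if e.kind == "insertion"]
        assert len(ins) == 1 and ins[0].length == 3
        # left-normalized anchor with the inserted bases preserved
        assert len(ins[0].alt) == 3

    def test_deletion_and_mismatch_are_distinct_events(self, coding_amplicon):
        read = substitute(delete(coding_amplicon.sequence, 30, 2), 80)
        events, _, _ = align_read(read, coding_amplicon)
        kinds = sorted(e.kind for e in events)
        assert kinds == ["deletion", "substitution"]

    def test_low_identity_read_flagged(self, coding_amplicon):
        rng = np.random.default_rng(23)
        garbage = "".join(rand_seq(rng, len(coding_amplicon)))
        rc = classify_read(
            ReadRecord("junk", garbage), coding_amplicon, []
        )
        assert rc is None

    def test_short_read_does_not_cover_window(self, coding_amplicon, target_a):
        # read covering only the first 40 reference bases
        read = coding_amplicon.sequence[:40]
        events, span, identity = align_read(read, coding_amplicon)
        call = classify_events(events, target_a, coding_amplicon, span)
        assert call.status == "not_covering"


class TestClassifyEvents:
    """Window/coding rules on the hand-built geometry: target A has cut
    c = 57, window [52, 62), coding [20, 58)."""

    def test_no_events_is_unmodified(self, coding_amplicon, target_a):
        call = classify_events([], target_a, coding_amplicon, FULL(coding_amplicon))
        assert call.status == "unmodified"

    def test_substitution_in_window_stays_unmodified(
        self, coding_amplicon, target_a
    ):
        events = [MutationEvent("substitution", 55, 1, "A")]
        call = classify_events(events, target_a, coding_amplicon, FULL(coding_amplicon))
        assert call.status == "unmodified"

    def test_one_nt_insertion_at_cut_in_coding_is_frameshift(
        self, coding_amplicon, target_a
    ):
        events = [MutationEvent("insertion", 57, 1, "A")]
        call = classify_events(events, target_a, coding_amplicon, FULL(coding_amplicon))
        assert (call.status, call.category) == ("mutated", "frameshift")
        assert call.net_coding_shift == 1

    def test_three_nt_coding_deletion_is_inframe(self, coding_amplicon, target_a):
        events = [MutationEvent("deletion", 52, 3)]
        call = classify_events(events, target_a, coding_amplicon, FULL(coding_amplicon))
        assert (call.status, call.category) == ("mutated", "inframe")
        assert call.net_coding_shift == -3

    def test_noncoding_window_deletion_is_noncoding(
        self, coding_amplicon, target_a
    ):
        # [59, 61) lies inside the window but beyond the coding end at 58
        events = [MutationEvent("deletion", 59, 2)]
        call = classify_events(events, target_a, coding_amplicon, FULL(coding_amplicon))
        assert (call.status, call.category) == ("mutated", "noncoding")
        assert call.net_coding_shift == 0

    def test_deletion_outside_window_is_unmodified(
        self, coding_amplicon, target_a
    ):
        events = [MutationEvent("deletion", 5, 4)]
        call = classify_events(events, target_a, coding_amplicon, FULL(coding_amplicon))
        assert call.status == "unmodified"

    def test_large_deletion_spanning_two_windows_counts_for_both(
        self, coding_amplicon, target_a, target_b
    ):
        # [58, 68) intersects window A [52, 62) and window B [62, 72)
        events = [MutationEvent("deletion", 58, 10)]
        span = FULL(coding_amplicon)
        call_a = classify_events(events, target_a, coding_amplicon, span)
        call_b = classify_events(events, target_b, coding_amplicon, span)
        assert call_a.status == "mutated"
        assert call_b.status == "mutated"

    def test_insertion_anchor_window_boundaries_inclusive(
        self, coding_amplicon, target_a
    ):
        for anchor, expected in [(52, "mutated"), (62, "mutated"), (63, "unmodified")]:
            call = classify_events(
                [MutationEvent("insertion", anchor, 2, "AT")],
                target_a,
                coding_amplicon,
                FULL(coding_amplicon),
            )
            assert call.status == expected, anchor

    def test_compound_indels_sum_net_shift(self, coding_amplicon, target_a):
        # -2 coding deletion plus +1 coding insertion: net -1, frameshift
        events = [
            MutationEvent("deletion", 53, 2),
            MutationEvent("insertion", 57, 1, "G"),
        ]
        call = classify_events(events, target_a, coding_amplicon, FULL(coding_amplicon))
        assert call.category == "frameshift"
        assert call.net_coding_shift == -1
        assert sorted(call.indel_sizes) == [-2, 1]


def _reads_for(amplicon, specs):
    """Build reads from (edit_fn | None) specs against the amplicon."""
    reads = []
    for i, fn in enumerate(specs):
        seq = amplicon.sequence if fn is None else fn(amplicon.sequence)
        reads.append(ReadRecord(f"r{i}", seq))
    return reads


class TestQuantifyAnimal:
    def test_hand_built_fraction_example(self, coding_amplicon, target_a):
        """4 unmodified + 3 frameshift + 2 in-frame + 1 noncoding reads."""
        specs = (
            [None] * 4
            + [lambda s: insert(s, 57, "A")] * 3
            + [lambda s: delete(s, 52, 3)] * 2
            + [lambda s: delete(s, 59, 2)]
        )
        reads = _reads_for(coding_amplicon, specs)
        aq = quantify_animal(
            "x",
            {coding_amplicon.amplicon_id: reads},
            {coding_amplicon.amplicon_id: coding_amplicon},
            [target_a],
            min_reads=1,
        )
        tq = aq.per_target["tA"]
        assert (tq.q, tq.fs, tq.im, tq.nm) == (0.4, 0.3, 0.2, 0.1)
        assert tq.mutation_rate == pytest.approx(0.6)
        assert tq.frameshift_of_mutated == pytest.approx(0.5)

    def test_all_unmodified(self, coding_amplicon, target_a):
        reads = _reads_for(coding_amplicon, [None] * 5)
        aq = quantify_animal(
            "x",
            {coding_amplicon.amplicon_id: reads},
            {coding_amplicon.amplicon_id: coding_amplicon},
            [target_a],
            min_reads=1,
        )
        tq = aq.per_target["tA"]
        assert tq.q == 1.0 and tq.mutation_rate == 0.0
        assert tq.frameshift_of_mutated is None

    def test_insufficient_coverage_marker_not_division_by_zero(
        self, coding_amplicon, target_a
    ):
        aq = quantify_animal(
            "x",
            {coding_amplicon.amplicon_id: []},
            {coding_amplicon.amplicon_id: coding_amplicon},
            [target_a],
        )
        assert aq.per_target == {}
        assert aq.insufficient == {"tA": 0}

    def test_conservation_of_fractions(self, coding_amplicon, target_a, target_b):
        rng = np.random.default_rng(31)
        edits = [
            None,
            lambda s: insert(s, 57, "AC"),
            lambda s: delete(s, 55, 6),
            lambda s: delete(s, 58, 10),
            lambda s: substitute(s, 54),
        ]
        specs = [edits[i] for i in rng.integers(0, len(edits), 60)]
        reads = _reads_for(coding_amplicon, specs)
        aq = quantify_animal(
            "x",
            {coding_amplicon.amplicon_id: reads},
            {coding_amplicon.amplicon_id: coding_amplicon},
            [target_a, target_b],
            min_reads=1,
        )
        for tq in aq.per_target.values():
            assert tq.q + tq.fs + tq.im + tq.nm == pytest.approx(1.0, abs=1e-12)

    def test_appending_frameshift_read_monotone(self, coding_amplicon, target_a):
        base = _reads_for(
            coding_amplicon, [None, None, lambda s: delete(s, 52, 3)]
        )
        fs_read = _reads_for(coding_amplicon, [lambda s: insert(s, 57, "A")])
        amps = {coding_amplicon.amplicon_id: coding_amplicon}

        def frac(reads):
            aq = quantify_animal(
                "x", {coding_amplicon.amplicon_id: reads}, amps, [target_a], min_reads=1
            )
            return aq.per_target["tA"]

        before, after = frac(base), frac(base + fs_read)
        assert after.fs >= before.fs
        assert after.q <= before.q

    def test_substitution_only_perturbations_never_change_fractions(
        self, coding_amplicon, target_a
    ):
        """SNS robustness: sprinkling substitutions on every read leaves
        every fraction unchanged."""
        rng = np.random.default_rng(37)
        specs = (
            [None] * 5
            + [lambda s: insert(s, 57, "A")] * 3
            + [lambda s: delete(s, 52, 3)] * 2
        )
        clean = _reads_for(coding_amplicon, specs)
        noisy = []
        for read in clean:
            seq = read.sequence
            for pos in rng.integers(0, len(seq), 3):
                seq = substitute(seq, int(pos))
            noisy.append(ReadRecord(read.read_id, seq))
        amps = {coding_amplicon.amplicon_id: coding_amplicon}

        def quant(reads):
            aq = quantify_animal(
                "x", {coding_amplicon.amplicon_id: reads}, amps, [target_a], min_reads=1
            )
            tq = aq.per_target["tA"]
            return (tq.q, tq.fs, tq.im, tq.nm)

        assert quant(clean) == quant(noisy)

    def test_recovers_true_wildtype_fraction(self, coding_amplicon, target_a):
        """Sampling 10,000 error-free reads from a pool with q = 0.30
        recovers q within the binomial bound (3 sigma ~ 0.014)."""
        mutated = insert(coding_amplicon.sequence, 57, "A")
        pool = AllelePool(
            animal_id="x",
            amplicon_id=coding_amplicon.amplicon_id,
            alleles=(
                Allele(coding_amplicon.sequence, {}, 0.30, {}),
                Allele(mutated, {}, 0.70, {}),
            ),
            theta={"tA": 0.7},
            truth={"tA": (0.30, 0.70, 0.0, 0.0)},
        )
        cfg = SimulationConfig(seed=0, substitution_rate=0.0)
        reads = simulate_reads(pool, cfg, np.random.default_rng(5), n_reads=10_000)
        aq = quantify_animal(
            "x",
            {coding_amplicon.amplicon_id: reads},
            {coding_amplicon.amplicon_id: coding_amplicon},
            [target_a],
        )
        assert aq.per_target["tA"].q == pytest.approx(0.30, abs=0.02)


def test_mean_quality_filter_drops_low_quality_reads(coding_amplicon, target_a):
    good = ReadRecord("hi", coding_amplicon.sequence, qualities=(38,) * 120)
    bad = ReadRecord("lo", coding_amplicon.sequence, qualities=(8,) * 120)
    aq = quantify_animal(
        "x",
        {coding_amplicon.amplicon_id: [good, bad]},
        {coding_amplicon.amplicon_id: coding_amplicon},
        [target_a],
        min_reads=1,
        min_mean_quality=20.0,
    )
    assert aq.per_target["tA"].n_reads == 1


class TestFastqIO:
    def test_fastq_gz_round_trip(self, tmp_path, coding_amplicon):
        reads = [
            ReadRecord("r1", coding_amplicon.sequence),
            ReadRecord("r2", delete(coding_amplicon.sequence, 52, 3)),
        ]
        path = tmp_path / "reads.fastq.gz"
        write_fastq_gz(reads, path)
        loaded = list(read_fastq(path))
        assert [(r.read_id, r.sequence) for r in loaded] == [
            (r.read_id, r.sequence) for r in reads
        ]
        assert loaded[0].qualities[0] == 40
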