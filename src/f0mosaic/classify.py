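"""Read alignment, event calling and per-target classification.

Each amplicon read is globally aligned to its reference with affine gap
penalties, indels are left-normalized to deterministic coordinates, and
the read is classified independently for every sgRNA target on the
amplicon:

* a read counts for a target only if its alignment fully spans the
  target's quantification window (otherwise ``not_covering``);
* the read is ``mutated`` for the target iff at least one insertion or
  deletion intersects the window; single-nucleotide substitutions are
  treated as sequencing/PCR noise and never change the status;
* a mutated read is ``frameshift`` when the summed coding-length change
  of its in-window indels is not a multiple of 3, ``inframe`` when it is
  a multiple of 3 and at least one in-window indel touches coding
  sequence, and ``noncoding`` when no in-window indel touches coding
  sequence.

Per animal and target this yields the allele fractions
``q`` (unmodified), ``fs`` (frameshift), ``im`` (in-frame) and ``nm``
(non-coding), with ``q + fs + im + nm = 1`` over covering reads — the
inputs of the biallelic loss-of-function model in :mod:`f0mosaic.lof`.

Identical read sequences are collapsed before alignment (amplicon data
from mosaic embryos is dominated by a handful of alleles), so cohorts of
millions of reads quantify in seconds.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from Bio import Align, SeqIO

from .amplicons import Amplicon, SgRNATarget, cleavage_site, quantification_window

__all__ = [
    "ReadRecord",
    "MutationEvent",
    "TargetCall",
    "ReadClassification",
    "TargetQuantification",
    "AnimalQuantification",
    "AlignmentScoring",
    "make_aligner",
    "align_read",
    "classify_events",
    "classify_read",
    "quantify_animal",
    "read_fastq",
    "DEFAULT_MIN_READS",
    "DEFAULT_MIN_IDENTITY",
]

DEFAULT_MIN_READS = 100
DEFAULT_MIN_IDENTITY = 0.60

Status = Literal["not_covering", "unmodified", "mutated"]
Category = Literal["frameshift", "inframe", "noncoding"]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read (FASTQ carrier)."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


@dataclass(frozen=True)
class MutationEvent:
    """One insertion, deletion or substitution relative to the reference.

    ``ref_start`` is a 0-based reference coordinate; for insertions it is
    the between-base anchor.  ``alt`` holds inserted or substituted bases
    and is empty for deletions.
    """

    kind: Literal["insertion", "deletion", "substitution"]
    ref_start: int
    length: int
    alt: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("event length must be >= 1")

    @property
    def signed_size(self) -> int:
        """+length for insertions, -length for deletions (indels only)."""
        if self.kind == "insertion":
            return self.length
        if self.kind == "deletion":
            return -self.length
        raise ValueError("substitutions have no signed size")


@dataclass(frozen=True)
class TargetCall:
    """Classification of one read with respect to one sgRNA target."""

    status: Status
    category: Category | None = None
    net_coding_shift: int = 0
    #: signed sizes of every in-window indel event (repeats preserved)
    indel_sizes: tuple[int, ...] = ()


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    calls: dict[str, TargetCall]  # target_id -> call


@dataclass(frozen=True)
class TargetQuantification:
    """Per-animal fractions for one target, over window-covering reads."""

    target_id: str
    n_reads: int
    q: float
    fs: float
    im: float
    nm: float

    @property
    def mutation_rate(self) -> float:
        return 1.0 - self.q

    @property
    def frameshift_of_mutated(self) -> float | None:
        """fs / (1 - q); None when no read is mutated."""
        if self.mutation_rate <= 0.0:
            return None
        return self.fs / self.mutation_rate


@dataclass
class AnimalQuantification:
    """Quantification of every panel target for one animal.

    Targets with fewer covering reads than ``min_reads`` are present in
    ``insufficient`` instead of ``per_target``.
    """

    animal_id: str
    per_target: dict[str, TargetQuantification] = field(default_factory=dict)
    insufficient: dict[str, int] = field(default_factory=dict)  # target -> n


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignmentScoring:
    """Global affine-gap scoring (a length-L gap scores open + (L-1)*extend)."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


def make_aligner(scoring: AlignmentScoring = AlignmentScoring()) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _left_normalize(event: MutationEvent, ref: str) -> MutationEvent:
    """Shift an indel to its leftmost equivalent placement on the reference."""
    if event.kind == "deletion":
        start, length = event.ref_start, event.length
        while start > 0 and ref[start - 1] == ref[start + length - 1]:
            start -= 1
        if start != event.ref_start:
            return MutationEvent("deletion", start, length)
        return event
    if event.kind == "insertion":
        anchor, alt = event.ref_start, event.alt
        while anchor > 0 and ref[anchor - 1] == alt[-1]:
            alt = alt[-1] + alt[:-1]
            anchor -= 1
        if anchor != event.ref_start:
            return MutationEvent("insertion", anchor, event.length, alt)
        return event
    return event


def align_read(
    read_seq: str,
    amplicon: Amplicon,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[MutationEvent], tuple[int, int], float]:
    """Globally align a read to the amplicon and call mutation events.

    Returns ``(events, ref_span, identity)`` where ``events`` are
    left-normalized :class:`MutationEvent` (maximal gap runs become single
    indels, mismatch columns become length-1 substitutions), ``ref_span``
    is the half-open reference interval the read actually covers
    (terminal gap runs are coverage, not deletions), and ``identity`` is
    the fraction of matching alignment columns.
    """
    ref = amplicon.sequence
    if read_seq == ref:  # fast path: the bulk of wildtype reads
        return [], (0, len(ref)), 1.0

    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(ref, read_seq)[0]
    ref_blocks, read_blocks = aln.aligned

    events: list[MutationEvent] = []
    matches = 0
    mismatches = 0
    gap_columns = 0

    # mismatch columns within aligned blocks become length-1 substitutions;
    # adjacent distinct events are never merged
    for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
        for i in range(re - rs):
            if ref[rs + i] != read_seq[qs + i]:
                mismatches += 1
                events.append(
                    MutationEvent("substitution", rs + i, 1, read_seq[qs + i])
                )
            else:
                matches += 1

    # gaps between consecutive blocks: ref gap -> insertion, read gap -> deletion
    for k in range(len(ref_blocks) - 1):
        r_end, r_next = ref_blocks[k][1], ref_blocks[k + 1][0]
        q_end, q_next = read_blocks[k][1], read_blocks[k + 1][0]
        if r_next > r_end:
            gap_columns += r_next - r_end
            events.append(MutationEvent("deletion", r_end, r_next - r_end))
        if q_next > q_end:
            gap_columns += q_next - q_end
            events.append(
                MutationEvent(
                    "insertion", r_end, q_next - q_end, read_seq[q_end:q_next]
                )
            )

    if ref_blocks.size:
        ref_span = (int(ref_blocks[0][0]), int(ref_blocks[-1][1]))
    else:  # pathological: nothing aligned
        ref_span = (0, 0)
    # terminal read overhangs hanging off the amplicon ends are ignored
    total_columns = matches + mismatches + gap_columns
    identity = matches / total_columns if total_columns else 0.0

    events = [_left_normalize(ev, ref) for ev in events]
    events.sort(key=lambda ev: (ev.ref_start, ev.kind))
    return events, ref_span, identity


# ---------------------------------------------------------------------------
# classification


def _coding_overlap(amplicon: Amplicon, start: int, end: int) -> int:
    """Number of coding bases in reference interval [start, end)."""
    total = 0
    for cs, ce in amplicon.coding_intervals:
        total += max(0, min(end, ce) - max(start, cs))
    return total


def _anchor_in_coding(amplicon: Amplicon, anchor: int) -> bool:
    """True iff the between-base anchor lies strictly inside a coding interval."""
    return any(cs < anchor < ce for cs, ce in amplicon.coding_intervals)


def classify_events(
    events: Iterable[MutationEvent],
    target: SgRNATarget,
    amplicon: Amplicon,
    ref_span: tuple[int, int],
) -> TargetCall:
    """Classify one read's events with respect to one target.

    A deletion is in-window iff it deletes at least one reference base in
    ``[c - w, c + w)``; an insertion iff its anchor lies in the closed
    range ``[c - w, c + w]``.  Substitutions never affect the status.
    """
    lo, hi = quantification_window(target, amplicon)
    if ref_span[0] > lo or ref_span[1] < hi:
        return TargetCall(status="not_covering")

    in_window: list[MutationEvent] = []
    for ev in events:
        if ev.kind == "deletion":
            if ev.ref_start < hi and ev.ref_start + ev.length > lo:
                in_window.append(ev)
        elif ev.kind == "insertion":
            if lo <= ev.ref_start <= hi:
                in_window.append(ev)
    if not in_window:
        return TargetCall(status="unmodified")

    net = 0
    touches_coding = False
    sizes = []
    for ev in in_window:
        sizes.append(ev.signed_size)
        if ev.kind == "insertion":
            if _anchor_in_coding(amplicon, ev.ref_start):
                net += ev.length
                touches_coding = True
        else:
            overlap = _coding_overlap(amplicon, ev.ref_start, ev.ref_start + ev.length)
            if overlap > 0:
                net -= overlap
                touches_coding = True

    if net % 3 != 0:
        category: Category = "frameshift"
    elif touches_coding:
        category = "inframe"
    else:
        category = "noncoding"
    return TargetCall(
        status="mutated",
        category=category,
        net_coding_shift=net,
        indel_sizes=tuple(sizes),
    )


def classify_read(
    read: ReadRecord,
    amplicon: Amplicon,
    targets: Iterable[SgRNATarget],
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ReadClassification | None:
    """Align one read and classify it for every target on the amplicon.

    Returns ``None`` for unalignable reads (identity below
    ``min_identity``); such reads enter no denominator.
    """
    events, ref_span, identity = align_read(read.sequence, amplicon, aligner)
    if identity < min_identity:
        return None
    calls = {
        t.target_id: classify_events(events, t, amplicon, ref_span)
        for t in targets
    }
    return ReadClassification(read_id=read.read_id, calls=calls)


# ---------------------------------------------------------------------------
# quantification


def _quantify_calls(
    target_id: str, calls: list[TargetCall], min_reads: int
) -> tuple[TargetQuantification | None, int]:
    covering = [c for c in calls if c.status != "not_covering"]
    n = len(covering)
    if n < min_reads:
        return None, n
    n_q = sum(1 for c in covering if c.status == "unmodified")
    n_fs = sum(1 for c in covering if c.category == "frameshift")
    n_im = sum(1 for c in covering if c.category == "inframe")
    n_nm = sum(1 for c in covering if c.category == "noncoding")
    return (
        TargetQuantification(
            target_id=target_id,
            n_reads=n,
            q=n_q / n,
            fs=n_fs / n,
            im=n_im / n,
            nm=n_nm / n,
        ),
        n,
    )


def quantify_animal(
    animal_id: str,
    reads_by_amplicon: dict[str, Iterable[ReadRecord]],
    amplicons: dict[str, Amplicon],
    targets: Iterable[SgRNATarget],
    min_reads: int = DEFAULT_MIN_READS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    scoring: AlignmentScoring = AlignmentScoring(),
    collect_classifications: bool = False,
    min_mean_quality: float | None = None,
) -> AnimalQuantification | tuple[AnimalQuantification, list[ReadClassification]]:
    """Quantify q/fs/im/nm for every panel target from one animal's reads.

    ``reads_by_amplicon`` maps amplicon id to that animal's reads for the
    amplicon.  Identical read sequences share one alignment.  With
    ``collect_classifications`` the per-read calls are also returned (for
    indel-spectrum profiling).  ``min_mean_quality`` optionally drops
    reads whose mean base quality falls below the threshold (off by
    default); dropped reads enter no denominator.
    """
    targets = list(targets)
    by_amp: dict[str, list[SgRNATarget]] = {}
    for t in targets:
        by_amp.setdefault(t.amplicon_id, []).append(t)

    aligner = make_aligner(scoring)
    calls_per_target: dict[str, list[TargetCall]] = {t.target_id: [] for t in targets}
    classifications: list[ReadClassification] = []

    for amplicon_id, amp_targets in by_amp.items():
        amplicon = amplicons[amplicon_id]
        reads = reads_by_amplicon.get(amplicon_id, ())
        cache: dict[str, ReadClassification | None] = {}
        missing = object()
        for read in reads:
            if (
                min_mean_quality is not None
                and read.qualities is not None
                and sum(read.qualities) / len(read.qualities) < min_mean_quality
            ):
                continue
            cached = cache.get(read.sequence, missing)
            if cached is missing:
                cached = classify_read(
                    read, amplicon, amp_targets, aligner, min_identity
                )
                cache[read.sequence] = cached
            if cached is None:  # unalignable: excluded from all denominators
                continue
            for tid, call in cached.calls.items():
                calls_per_target[tid].append(call)
            if collect_classifications:
                classifications.append(
                    ReadClassification(read_id=read.read_id, calls=cached.calls)
                )

    aq = AnimalQuantification(animal_id=animal_id)
    for t in targets:
        tq, n = _quantify_calls(t.target_id, calls_per_target[t.target_id], min_reads)
        if tq is None:
            aq.insufficient[t.target_id] = n
        else:
            aq.per_target[t.target_id] = tq
    if collect_classifications:
        return aq, classifications
    return aq


# ---------------------------------------------------------------------------
# FASTQ input


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ or gzipped FASTQ file."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = rec.letter_annotations.get("phred_quality")
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=tuple(quals) if quals else None,
            )
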