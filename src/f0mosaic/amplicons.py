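"""Amplicon and sgRNA-target geometry.

An :class:`Amplicon` is the reference sequence of one deep-sequencing
amplicon together with the coding intervals it carries.  An
:class:`SgRNATarget` places a 20-nt SpCas9 protospacer (NGG PAM) on that
amplicon.  From the placement we derive the predicted blunt cut site —
between the third and fourth nucleotide upstream of the PAM — and the
quantification window around it, inside which indels are attributed to
nuclease activity.

Coordinate conventions, used throughout the package:

* all reference coordinates are 0-based, half-open;
* cut sites are *between-base* integers: cut ``c`` lies between reference
  positions ``c - 1`` and ``c``;
* the quantification window with half-width ``w`` is the interval
  ``[c - w, c + w)`` of ``2 w`` reference positions; an insertion is
  in-window iff its between-base anchor lies in the closed range
  ``[c - w, c + w]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Amplicon",
    "SgRNATarget",
    "TargetValidationError",
    "validate_target",
    "cleavage_site",
    "quantification_window",
    "load_amplicons",
    "load_targets",
    "revcomp",
]

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: distance of the blunt cut from the PAM-proximal protospacer end
CUT_OFFSET = 3
DEFAULT_WINDOW_HALFWIDTH = 5

_VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


class TargetValidationError(ValueError):
    """Protospacer/PAM placement disagrees with the amplicon reference."""


@dataclass(frozen=True)
class Amplicon:
    """One amplicon reference sequence with its coding intervals.

    Parameters
    ----------
    amplicon_id
        Name used in FASTA headers, BED chrom column and sample sheets.
    sequence
        Uppercase ACGT reference sequence, at least 50 nt.
    coding_intervals
        Sorted, pairwise-disjoint 0-based half-open intervals of coding
        sequence on the amplicon.  May be empty (purely non-coding
        amplicon, e.g. an off-target control).
    """

    amplicon_id: str
    sequence: str
    coding_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < 50:
            raise ValueError(
                f"amplicon {self.amplicon_id!r}: sequence shorter than 50 nt"
            )
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(
                f"amplicon {self.amplicon_id!r}: non-ACGT characters {bad}"
            )
        object.__setattr__(
            self, "coding_intervals", tuple(map(tuple, self.coding_intervals))
        )
        prev_end = 0
        for start, end in self.coding_intervals:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"amplicon {self.amplicon_id!r}: coding interval "
                    f"[{start}, {end}) outside [0, {len(self.sequence)})"
                )
            if start < prev_end:
                raise ValueError(
                    f"amplicon {self.amplicon_id!r}: coding intervals must be "
                    "sorted and disjoint"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SgRNATarget:
    """Placement of one sgRNA protospacer on an amplicon.

    ``pam_start`` is the 0-based index of the PAM's first reference base.
    For a ``+`` target the PAM occupies ``[pam_start, pam_start + 3)``
    directly 3' of the protospacer; for a ``-`` target the PAM occupies the
    three reference bases whose reverse complement reads NGG, directly 5'
    (in reference orientation) of the protospacer.
    """

    target_id: str
    amplicon_id: str
    protospacer: str
    strand: str
    pam_start: int
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"target {self.target_id!r}: strand must be + or -")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"target {self.target_id!r}: protospacer must be "
                f"{PROTOSPACER_LEN} nt, got {len(self.protospacer)}"
            )
        if self.window_halfwidth < 1:
            raise ValueError(
                f"target {self.target_id!r}: window_halfwidth must be >= 1"
            )

    @property
    def protospacer_start(self) -> int:
        """Reference start of the protospacer (both strands)."""
        if self.strand == "+":
            return self.pam_start - PROTOSPACER_LEN
        return self.pam_start + PAM_LEN


def validate_target(target: SgRNATarget, amplicon: Amplicon) -> SgRNATarget:
    """Check protospacer and PAM against the amplicon reference.

    Returns the target unchanged if the protospacer matches the reference
    at its implied location (reverse complement for ``-``) and the PAM
    reads NGG on the target strand; raises
    :class:`TargetValidationError` naming the offending coordinates
    otherwise.
    """
    if target.amplicon_id != amplicon.amplicon_id:
        raise TargetValidationError(
            f"target {target.target_id!r} references amplicon "
            f"{target.amplicon_id!r}, not {amplicon.amplicon_id!r}"
        )
    s = target.protospacer_start
    if target.strand == "+":
        pam_slice = slice(target.pam_start, target.pam_start + PAM_LEN)
        ref_pam = amplicon.sequence[pam_slice]
        ref_proto = amplicon.sequence[s : s + PROTOSPACER_LEN]
        expected_proto = target.protospacer
    else:
        pam_slice = slice(target.pam_start, target.pam_start + PAM_LEN)
        ref_pam = revcomp(amplicon.sequence[pam_slice])
        ref_proto = amplicon.sequence[s : s + PROTOSPACER_LEN]
        expected_proto = revcomp(target.protospacer)
    if s < 0 or s + PROTOSPACER_LEN > len(amplicon):
        raise TargetValidationError(
            f"target {target.target_id!r}: protospacer span "
            f"[{s}, {s + PROTOSPACER_LEN}) outside amplicon of length "
            f"{len(amplicon)}"
        )
    if len(ref_pam) != PAM_LEN or not (ref_pam[1:] == "GG"):
        raise TargetValidationError(
            f"target {target.target_id!r}: reference bases at "
            f"[{pam_slice.start}, {pam_slice.stop}) read {ref_pam!r} on the "
            "target strand, expected NGG"
        )
    if ref_proto != expected_proto:
        raise TargetValidationError(
            f"target {target.target_id!r}: protospacer mismatch at reference "
            f"[{s}, {s + PROTOSPACER_LEN}): amplicon has {ref_proto!r}"
        )
    return target


def cleavage_site(target: SgRNATarget) -> int:
    """Between-base coordinate of the predicted blunt cut.

    SpCas9 cuts between the third and fourth nucleotide upstream of the
    PAM.  With the protospacer on the reference at ``[s, s + 20)``:
    ``+`` strand gives ``c = s + 17`` and ``-`` strand the mirror image
    ``c = s + 3``.
    """
    s = target.protospacer_start
    if target.strand == "+":
        return s + PROTOSPACER_LEN - CUT_OFFSET
    return s + CUT_OFFSET


def quantification_window(
    target: SgRNATarget, amplicon: Amplicon
) -> tuple[int, int]:
    """Reference interval ``[c - w, c + w)`` around the cut site.

    Raises ``ValueError`` if the window extends beyond the amplicon (the
    amplicon is too short for this target).
    """
    c = cleavage_site(target)
    w = target.window_halfwidth
    lo, hi = c - w, c + w
    if lo < 0 or hi > len(amplicon):
        raise ValueError(
            f"target {target.target_id!r}: quantification window [{lo}, {hi}) "
            f"extends beyond amplicon of length {len(amplicon)}"
        )
    return lo, hi


# ---------------------------------------------------------------------------
# file loading


def load_amplicons(fasta_path, bed_path=None) -> dict[str, Amplicon]:
    """Load amplicons from FASTA plus optional coding-interval BED.

    The BED file is 0-based half-open with the amplicon id in the chrom
    column; only the first three columns are used.
    """
    coding: dict[str, list[tuple[int, int]]] = {}
    if bed_path is not None:
        bed = pd.read_csv(
            bed_path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": int, "end": int},
        )
        for row in bed.itertuples(index=False):
            coding.setdefault(row.chrom, []).append((row.start, row.end))
    amplicons = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        amplicons[rec.id] = Amplicon(
            amplicon_id=rec.id,
            sequence=seq,
            coding_intervals=tuple(sorted(coding.get(rec.id, []))),
        )
    if not amplicons:
        raise ValueError(f"no sequences found in {fasta_path}")
    unknown = set(coding) - set(amplicons)
    if unknown:
        raise ValueError(f"BED references unknown amplicons: {sorted(unknown)}")
    return amplicons


def load_targets(
    tsv_path, window_halfwidth: int | None = None
) -> list[SgRNATarget]:
    """Load the sgRNA panel from TSV.

    Expected columns: ``target_id``, ``amplicon_id``, ``protospacer``,
    ``strand``, ``pam_start`` (0-based).  ``window_halfwidth`` overrides
    the default half-width for every target when given.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"protospacer": str})
    required = {"target_id", "amplicon_id", "protospacer", "strand", "pam_start"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    targets = []
    for row in df.itertuples(index=False):
        t = SgRNATarget(
            target_id=str(row.target_id),
            amplicon_id=str(row.amplicon_id),
            protospacer=str(row.protospacer).upper(),
            strand=str(row.strand),
            pam_start=int(row.pam_start),
        )
        if window_halfwidth is not None:
            t = replace(t, window_halfwidth=window_halfwidth)
        targets.append(t)
    return targets
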