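"""Shared fixtures: deterministic hand-built amplicons and edit helpers."""

from __future__ import annotations

import numpy as np
import pytest

from f0mosaic import Amplicon, SgRNATarget, validate_target


def rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return ["ACGT"[i] for i in rng.integers(0, 4, n)]


def delete(seq: str, start: int, length: int) -> str:
    return seq[:start] + seq[start + length :]


def insert(seq: str, anchor: int, alt: str) -> str:
    return seq[:anchor] + alt + seq[anchor:]


def substitute(seq: str, pos: int) -> str:
    new = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return seq[:pos] + new + seq[pos + 1 :]


@pytest.fixture(scope="session")
def coding_amplicon() -> Amplicon:
    """120-nt amplicon, coding [20, 58), with two plantable + PAMs.

    Geometry: a '+' target with protospacer [40, 60) and PAM [60, 63) has
    cut c = 57 and window [52, 62); positions 52-57 are coding, 58-61
    non-coding.  A second '+' target with protospacer [50, 70) and PAM
    [70, 73) has cut c = 67 and window [62, 72).
    """
    rng = np.random.default_rng(42)
    seq = rand_seq(rng, 120)
    seq[61] = seq[62] = "G"  # PAM for target A at [60, 63)
    seq[71] = seq[72] = "G"  # PAM for target B at [70, 73)
    return Amplicon("amp_coding", "".join(seq), ((20, 58),))


@pytest.fixture(scope="session")
def target_a(coding_amplicon) -> SgRNATarget:
    """'+' target, cut c = 57, window [52, 62)."""
    t = SgRNATarget(
        target_id="tA",
        amplicon_id=coding_amplicon.amplicon_id,
        protospacer=coding_amplicon.sequence[40:60],
        strand="+",
        pam_start=60,
    )
    return validate_target(t, coding_amplicon)


@pytest.fixture(scope="session")
def target_b(coding_amplicon) -> SgRNATarget:
    """'+' target, cut c = 67, window [62, 72)."""
    t = SgRNATarget(
        target_id="tB",
        amplicon_id=coding_amplicon.amplicon_id,
        protospacer=coding_amplicon.sequence[50:70],
        strand="+",
        pam_start=70,
    )
    return validate_target(t, coding_amplicon)


@pytest.fixture(scope="session")
def minus_amplicon() -> Amplicon:
    """80-nt amplicon carrying a '-' target: ref [7, 10) = CCT (revcomp
    AGG), protospacer on the reference at [10, 30), cut c = 13."""
    rng = np.random.default_rng(7)
    seq = rand_seq(rng, 80)
    seq[7], seq[8], seq[9] = "C", "C", "T"
    return Amplicon("amp_minus", "".join(seq), ((0, 80),))


@pytest.fixture(scope="session")
def minus_target(minus_amplicon) -> SgRNATarget:
    from f0mosaic import revcomp

    t = SgRNATarget(
        target_id="tMinus",
        amplicon_id=minus_amplicon.amplicon_id,
        protospacer=revcomp(minus_amplicon.sequence[10:30]),
        strand="-",
        pam_start=7,
    )
    return validate_target(t, minus_amplicon)
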