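"""sgRNA-specific indel spectra across a cohort.

CRISPR repair outcomes are locus-specific: microhomology-mediated end
joining favours recurrent deletions whose per-animal weight varies
widely, and deletions outnumber insertions roughly 4:1.  This module
summarizes those spectra from classified reads:

* per animal, the fraction of mutated reads carrying an in-window indel
  of each signed size (negative = deletion length, positive = insertion
  length); a read with several distinct indels contributes to each size,
  so fractions may sum above 1;
* per cohort, the mean of those per-animal fractions over animals that
  had at least one mutated read, plus the event-level
  deletion/insertion split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ReadClassification

__all__ = [
    "IndelProfile",
    "per_animal_indel_fractions",
    "cohort_indel_profile",
    "deletion_insertion_split",
    "profile_table",
]


@dataclass(frozen=True)
class IndelProfile:
    """Cohort-level indel spectrum for one sgRNA target."""

    target_id: str
    #: signed size -> mean over animals of per-animal fraction of mutated reads
    size_frequencies: dict[int, float]
    #: event-level shares over all in-window indel events; None if no events
    deletion_fraction: float | None
    insertion_fraction: float | None
    #: (size, mean frequency) of the most frequent indel; None if empty
    top_indel: tuple[int, float] | None
    n_animals: int


def per_animal_indel_fractions(
    classifications: Iterable[ReadClassification], target_id: str
) -> dict[int, float]:
    """Per-size fractions of one animal's mutated reads for one target.

    The denominator is the number of reads mutated for the target.  Each
    read counts at most once per size (a read carrying two distinct
    indels of the same size still contributes 1 to that size), so every
    fraction is <= 1 although the fractions of different sizes may sum
    above 1.  Returns an empty map when no read is mutated.
    """
    n_mutated = 0
    counts: dict[int, int] = {}
    for rc in classifications:
        call = rc.calls.get(target_id)
        if call is None or call.status != "mutated":
            continue
        n_mutated += 1
        for size in set(call.indel_sizes):
            counts[size] = counts.get(size, 0) + 1
    if n_mutated == 0:
        return {}
    return {size: n / n_mutated for size, n in sorted(counts.items())}


def _top_indel(size_frequencies: Mapping[int, float]) -> tuple[int, float] | None:
    if not size_frequencies:
        return None
    # ties broken toward smaller |size|, deletions before insertions
    best = max(
        size_frequencies.items(),
        key=lambda kv: (kv[1], -abs(kv[0]), kv[0] < 0),
    )
    return best


def cohort_indel_profile(
    per_animal_maps: Sequence[Mapping[int, float]],
    target_id: str = "",
    deletion_insertion: tuple[float, float] | None = None,
) -> IndelProfile:
    """Mean indel spectrum over animals with at least one mutated read.

    ``per_animal_maps`` holds one size->fraction map per contributing
    animal (empty maps — animals with zero mutated reads — are ignored; a
    fraction of zero reads is undefined).  A size absent from an animal's
    map counts as 0 in that animal.
    """
    contributing = [m for m in per_animal_maps if m]
    if not contributing:
        raise ValueError("no animal with mutated reads")
    n = len(contributing)
    sums: dict[int, float] = {}
    for m in contributing:
        for size, frac in m.items():
            if size == 0:
                raise ValueError("indel size 0 is not a valid event")
            sums[size] = sums.get(size, 0.0) + frac
    means = {size: s / n for size, s in sorted(sums.items())}
    del_frac, ins_frac = (None, None) if deletion_insertion is None else deletion_insertion
    return IndelProfile(
        target_id=target_id,
        size_frequencies=means,
        deletion_fraction=del_frac,
        insertion_fraction=ins_frac,
        top_indel=_top_indel(means),
        n_animals=n,
    )


def deletion_insertion_split(
    classifications: Iterable[ReadClassification], target_id: str
) -> tuple[float, float] | None:
    """Event-level (deletion_fraction, insertion_fraction) for one target.

    Counts every in-window indel event over all animals' mutated reads
    (repeated sizes within a read count separately).  Returns ``None``
    when there is no event at all.
    """
    n_del = 0
    n_ins = 0
    for rc in classifications:
        call = rc.calls.get(target_id)
        if call is None or call.status != "mutated":
            continue
        for size in call.indel_sizes:
            if size < 0:
                n_del += 1
            else:
                n_ins += 1
    total = n_del + n_ins
    if total == 0:
        return None
    return n_del / total, n_ins / total


def profile_table(profiles: Iterable[IndelProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long per-size table and per-target summary table for output.

    Returns ``(sizes, summary)``: ``sizes`` has columns ``target_id``,
    ``size``, ``mean_frequency``; ``summary`` has ``target_id``,
    ``deletion_fraction``, ``insertion_fraction``, ``top_indel_size``,
    ``top_indel_frequency``, ``n_animals``.
    """
    size_rows = []
    summary_rows = []
    for prof in profiles:
        for size, freq in prof.size_frequencies.items():
            size_rows.append(
                {"target_id": prof.target_id, "size": size, "mean_frequency": freq}
            )
        summary_rows.append(
            {
                "target_id": prof.target_id,
                "deletion_fraction": prof.deletion_fraction,
                "insertion_fraction": prof.insertion_fraction,
                "top_indel_size": None if prof.top_indel is None else prof.top_indel[0],
                "top_indel_frequency": None if prof.top_indel is None else prof.top_indel[1],
                "n_animals": prof.n_animals,
            }
        )
    return pd.DataFrame(size_rows), pd.DataFrame(summary_rows)
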