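"""Biallelic loss-of-function probability model for mosaic F0 animals.

A diploid F0 animal carries two allele pools sampled from the same mosaic
distribution of repair outcomes.  Treating the per-sgRNA wildtype
fraction ``q_r`` as the probability that a given allele escaped sgRNA
``r``, the probability that at least one mutation hit *each* allele when
``R`` sgRNAs were injected together is

    P(M) = (1 - prod_r q_r) ** 2

and the probability of at least one *frameshift* mutation on each allele —
discounting in-frame (``im``) and non-coding (``nm``) mutated fractions,
which do not disrupt the reading frame —

    P(F) = (1 - prod_r (q_r + im_r + nm_r)) ** 2

For a single sgRNA these reduce to ``(1 - q)**2`` and
``(1 - (q + im + nm))**2``.  ``q``, ``im`` and ``nm`` are fractions of
all covering reads, so ``q + im + nm <= 1`` per sgRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import AnimalQuantification

__all__ = [
    "LofEstimate",
    "p_mut",
    "p_fs",
    "animal_lof",
    "cohort_summary",
    "lof_table",
    "as_percent",
    "POOLED_SCOPE",
]

POOLED_SCOPE = "pooled"
_TOL = 1e-9


def as_percent(p: float) -> float:
    """Probability -> percentage rounded to one decimal (report format)."""
    return round(100.0 * p, 1)


def _check_unit(name: str, values: Sequence[float]) -> None:
    for v in values:
        if not (-_TOL <= v <= 1.0 + _TOL):
            raise ValueError(f"{name} value {v} outside [0, 1]")


def p_mut(q_list: Sequence[float]) -> float:
    """P(M): probability of >= 1 mutation on each of the two alleles.

    ``q_list`` holds the per-sgRNA wildtype (unmodified) fractions of the
    pooled panel; a single-element list gives the single-sgRNA form
    ``(1 - q)**2``.
    """
    if len(q_list) < 1:
        raise ValueError("at least one sgRNA required")
    _check_unit("q", q_list)
    return (1.0 - math.prod(q_list)) ** 2


def p_fs(
    q_list: Sequence[float],
    im_list: Sequence[float],
    nm_list: Sequence[float],
) -> float:
    """P(F): probability of >= 1 frameshift mutation on each allele.

    Per sgRNA the non-frameshift fraction is ``q + im + nm`` (wildtype,
    in-frame mutated, non-coding mutated); each must be a valid
    probability.
    """
    if not (len(q_list) == len(im_list) == len(nm_list) >= 1):
        raise ValueError("q, im, nm must have equal length >= 1")
    _check_unit("q", q_list)
    _check_unit("im", im_list)
    _check_unit("nm", nm_list)
    prod = 1.0
    for q, im, nm in zip(q_list, im_list, nm_list):
        s = q + im + nm
        if s > 1.0 + _TOL:
            raise ValueError(f"q + im + nm = {s} exceeds 1")
        prod *= min(s, 1.0)
    return (1.0 - prod) ** 2


@dataclass(frozen=True)
class LofEstimate:
    """P(M)/P(F) for one animal (or a cohort median) and one scope.

    ``scope`` is a single target id or :data:`POOLED_SCOPE` for the whole
    sgRNA panel.
    """

    animal_id: str
    scope: str
    p_mut: float
    p_fs: float

    def __post_init__(self) -> None:
        if not (-_TOL <= self.p_fs <= self.p_mut + _TOL <= 1.0 + 2 * _TOL):
            raise ValueError(
                f"invalid estimate: need 0 <= p_fs <= p_mut <= 1, got "
                f"p_fs={self.p_fs}, p_mut={self.p_mut}"
            )


def animal_lof(
    aq: AnimalQuantification, panel: Sequence[str] | None = None
) -> list[LofEstimate]:
    """Single-sgRNA and pooled estimates for one quantified animal.

    ``panel`` fixes the target order (defaults to the quantified
    targets).  The pooled estimate is omitted when any panel target has
    insufficient coverage; single-target estimates are produced for every
    covered target.
    """
    if panel is None:
        panel = list(aq.per_target)
    estimates = []
    q_list, im_list, nm_list = [], [], []
    pooled_ok = True
    for tid in panel:
        tq = aq.per_target.get(tid)
        if tq is None:
            pooled_ok = False
            continue
        estimates.append(
            LofEstimate(
                animal_id=aq.animal_id,
                scope=tid,
                p_mut=p_mut([tq.q]),
                p_fs=p_fs([tq.q], [tq.im], [tq.nm]),
            )
        )
        q_list.append(tq.q)
        im_list.append(tq.im)
        nm_list.append(tq.nm)
    if pooled_ok and q_list:
        estimates.append(
            LofEstimate(
                animal_id=aq.animal_id,
                scope=POOLED_SCOPE,
                p_mut=p_mut(q_list),
                p_fs=p_fs(q_list, im_list, nm_list),
            )
        )
    return estimates


def _median(values: Sequence[float]) -> float:
    # numpy's median uses the even-n midpoint convention
    return float(np.median(np.asarray(values, dtype=float)))


def cohort_summary(estimates: Iterable[LofEstimate]) -> pd.DataFrame:
    """Cohort medians of P(M)/P(F) per scope.

    Medians use the midpoint-of-central-pair convention for even n; note
    that a median of per-animal ``(1 - q)**2`` values is generally not
    ``(1 - median q)**2``, so medians computed here can differ slightly
    from applying the formula to a median mutagenesis rate.

    Returns a DataFrame with columns ``scope``, ``n_animals``,
    ``median_p_mut``, ``median_p_fs``, ``median_p_mut_pct``,
    ``median_p_fs_pct`` (percentages rounded to one decimal).
    """
    by_scope: dict[str, list[LofEstimate]] = {}
    for est in estimates:
        by_scope.setdefault(est.scope, []).append(est)
    if not by_scope:
        raise ValueError("empty cohort")
    rows = []
    for scope, ests in by_scope.items():
        med_m = _median([e.p_mut for e in ests])
        med_f = _median([e.p_fs for e in ests])
        rows.append(
            {
                "scope": scope,
                "n_animals": len(ests),
                "median_p_mut": med_m,
                "median_p_fs": med_f,
                "median_p_mut_pct": as_percent(med_m),
                "median_p_fs_pct": as_percent(med_f),
            }
        )
    return pd.DataFrame(rows)


def lof_table(fractions: pd.DataFrame) -> pd.DataFrame:
    """Per-animal LoF estimates from a fraction table (standalone entry).

    ``fractions`` needs columns ``animal_id``, ``target_id``, ``q``,
    ``im``, ``nm``.  Returns a long DataFrame with columns ``animal_id``,
    ``scope``, ``p_mut``, ``p_fs`` containing one row per
    (animal, target) plus one pooled row per animal.
    """
    required = {"animal_id", "target_id", "q", "im", "nm"}
    missing = required - set(fractions.columns)
    if missing:
        raise ValueError(f"fraction table missing columns: {sorted(missing)}")
    rows = []
    for animal_id, grp in fractions.groupby("animal_id", sort=False):
        q = grp["q"].tolist()
        im = grp["im"].tolist()
        nm = grp["nm"].tolist()
        for i, tid in enumerate(grp["target_id"]):
            rows.append(
                {
                    "animal_id": animal_id,
                    "scope": tid,
                    "p_mut": p_mut([q[i]]),
                    "p_fs": p_fs([q[i]], [im[i]], [nm[i]]),
                }
            )
        rows.append(
            {
                "animal_id": animal_id,
                "scope": POOLED_SCOPE,
                "p_mut": p_mut(q),
                "p_fs": p_fs(q, im, nm),
            }
        )
    return pd.DataFrame(rows)
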