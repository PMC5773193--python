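"""Normalized microcephaly index from morphometric measurements.

The microcephaly index (MI) of a larva is its head-diameter to
body-length ratio divided by the mean ratio of the uninjected/wildtype
control group, so the control group has mean MI = 1 by construction and
the index is invariant to any uniform magnification of both
measurements.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["microcephaly_index", "group_summary", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("animal_id", "group", "head_diameter", "body_length")


def _validate(records: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if (records["head_diameter"] <= 0).any() or (records["body_length"] <= 0).any():
        raise ValueError("measurements must be positive")
    bad = records["head_diameter"] >= records["body_length"]
    if bad.any():
        ids = records.loc[bad, "animal_id"].tolist()
        raise ValueError(f"head diameter not smaller than body length for {ids}")


def microcephaly_index(
    records: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Add ``ratio`` and ``mi`` columns, normalized to the control mean.

    ``records`` needs columns ``animal_id``, ``group``, ``head_diameter``
    and ``body_length`` in consistent (arbitrary) units.  Raises
    ``ValueError`` when the control group is empty.
    """
    _validate(records)
    out = records.copy()
    out["ratio"] = out["head_diameter"] / out["body_length"]
    control = out.loc[out["group"] == control_group, "ratio"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no records")
    out["mi"] = out["ratio"] / control.mean()
    return out


def group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group median MI and group size.

    Medians use the midpoint-of-central-pair convention for even n
    (pandas/numpy default).
    """
    if "mi" not in records.columns:
        raise ValueError("run microcephaly_index first (no 'mi' column)")
    return (
        records.groupby("group")["mi"]
        .agg(median_mi="median", n="size")
        .reset_index()
    )
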