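"""Genomic interval utilities.

All coordinates are 0-based, half-open (BED convention), both in memory and
on disk.  Region sets are plain :class:`pandas.DataFrame` objects with at
least ``chrom``, ``start`` and ``end`` columns; extra columns ride along.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGION_COLS = ["chrom", "start", "end"]


def as_region_frame(df: pd.DataFrame, sort: bool = True) -> pd.DataFrame:
    """Validate and (optionally) coordinate-sort a region frame."""
    missing = [c for c in REGION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"region frame missing columns: {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["end"] <= out["start"]).any():
        bad = out.index[(out["end"] <= out["start"])][0]
        raise ValueError(f"empty or inverted interval at row {bad}")
    if sort:
        out = out.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return out


def merge_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals into a minimal cover."""
    df = as_region_frame(df)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cs, ce = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= ce:
                ce = max(ce, e)
            else:
                rows.append((chrom, cs, ce))
                cs, ce = s, e
        rows.append((chrom, cs, ce))
    return pd.DataFrame(rows, columns=REGION_COLS)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap any subject interval?

    Overlap means a shared base: ``q.start < s.end and s.start < q.end``.
    """
    query = as_region_frame(query, sort=False)
    if len(subject) == 0:
        return np.zeros(len(query), dtype=bool)
    merged = merge_regions(subject)
    out = np.zeros(len(query), dtype=bool)
    by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in merged.groupby("chrom")}
    for i, (chrom, qs, qe) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        # merged intervals are disjoint and sorted, so ends are sorted too
        j = np.searchsorted(starts, qe, side="left")  # subjects with start < qe
        out[i] = j > 0 and ends[j - 1] > qs
    return out


def contains(outer: tuple, inner: tuple) -> bool:
    """Full containment of half-open ``inner`` within ``outer`` (chrom, start, end)."""
    return outer[0] == inner[0] and outer[1] <= inner[1] and inner[2] <= outer[2]


def reciprocal_overlap_fraction(a: tuple, b: tuple) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 if chromosomes differ."""
    if a[0] != b[0]:
        return 0.0
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return 0.0
    return min(ov / (a[2] - a[1]), ov / (b[2] - b[1]))
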