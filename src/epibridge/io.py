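"""Readers and writers for the package's on-disk formats.

Beta matrices and label tables are TSV; region sets are BED-like TSV
(0-based, half-open, sorted); sparse count matrices are MatrixMarket MTX
with a BED region sidecar and a TSV cell-metadata sidecar; reports are
JSON.  Every write/read pair round-trips the documented fields exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .regions import REGION_COLS, as_region_frame
from .synth import BetaMatrix, CellMatrix


# -- beta matrix ------------------------------------------------------------


def write_beta(beta: BetaMatrix, beta_path, groups_path) -> None:
    df = beta.loci.copy()
    for i, s in enumerate(beta.samples):
        df[s] = beta.values[:, i]
    df.to_csv(beta_path, sep="\t", index=False)
    pd.DataFrame({"sample": beta.samples, "group": beta.group}).to_csv(
        groups_path, sep="\t", index=False
    )


def read_beta(beta_path, groups_path) -> BetaMatrix:
    df = pd.read_csv(beta_path, sep="\t")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"beta TSV missing '{col}' column")
    groups = pd.read_csv(groups_path, sep="\t")
    samples = list(groups["sample"])
    missing = [s for s in samples if s not in df.columns]
    if missing:
        raise ValueError(f"beta TSV missing sample columns: {missing}")
    values = df[samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(values) < 0 or np.nanmax(values) > 1:
            raise ValueError("beta values outside [0, 1]")
    loci = df[["chrom", "pos"]].copy()
    for _, sub in loci.groupby("chrom"):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError("positions must be strictly increasing per chromosome")
    return BetaMatrix(
        loci=loci, values=values, samples=samples, group=groups["group"].to_numpy()
    )


# -- BED --------------------------------------------------------------------


def write_bed(regions: pd.DataFrame, path) -> None:
    """BED-like TSV: chrom/start/end first, extra columns after, no header
    for the canonical three columns alone, header otherwise."""
    regions = as_region_frame(regions)
    extra = [c for c in regions.columns if c not in REGION_COLS]
    cols = REGION_COLS + extra
    regions[cols].to_csv(path, sep="\t", index=False, header=bool(extra))


def read_bed(path, on_unsorted: str = "sort") -> pd.DataFrame:
    """Read a BED-like TSV (with or without header).

    ``on_unsorted``: 'sort' (default; warns and sorts) or 'error'.
    Malformed lines raise with their 1-based line number.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first.startswith("chrom")
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None, dtype={0: str}
    )
    if not has_header:
        if df.shape[1] < 3:
            raise ValueError(f"{path}: need >=3 BED columns")
        df.columns = REGION_COLS + [f"col{i}" for i in range(3, df.shape[1])]
    for lineno, row in enumerate(df.itertuples(index=False), start=2 if has_header else 1):
        try:
            s, e = int(row.start), int(row.end)
        except (ValueError, TypeError):
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
        if e <= s or s < 0:
            raise ValueError(f"{path}:{lineno}: invalid interval [{s}, {e})")
    sorted_df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        if on_unsorted == "error":
            raise ValueError(f"{path}: BED not coordinate-sorted")
        warnings.warn(f"{path}: BED not coordinate-sorted; sorting on read")
    return as_region_frame(sorted_df)


# -- MTX bundle -------------------------------------------------------------


def write_mtx_bundle(matrix: CellMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "counts.mtx", matrix.counts)
    write_bed(matrix.regions, outdir / "regions.bed")
    matrix.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_mtx_bundle(outdir) -> CellMatrix:
    outdir = Path(outdir)
    counts = sparse.csr_matrix(spio.mmread(outdir / "counts.mtx"))
    counts.eliminate_zeros()  # explicit zeros normalized away
    regions = read_bed(outdir / "regions.bed")
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t")
    return CellMatrix(regions=regions, cells=cells, counts=counts)


# -- generic tables and reports --------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, tuple)):
            return sorted(map(str, o))
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
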