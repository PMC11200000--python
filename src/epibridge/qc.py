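"""Single-cell RNA quality-control filtering.

Cells are removed when mitochondrial read fraction exceeds 10%, UMI
count falls below 600 or above 5000, or detected gene count exceeds
5000 — strict inequalities, so boundary values pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QcThresholds:
    max_mito_fraction: float = 0.10
    min_umi: int = 600
    max_umi: int = 5000
    max_genes: int = 5000

    def validate(self) -> None:
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")


def qc_filter_cells(stats: pd.DataFrame, thresholds: QcThresholds | None = None):
    """Partition cells into kept/removed by the QC predicate.

    ``stats`` needs per-cell columns ``umi``, ``genes``, ``mito_frac``.
    Returns ``(kept, removed, counts)`` where counts itemizes the reason
    tallies (a cell may fail several criteria).
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    for col in ("umi", "genes", "mito_frac"):
        if col not in stats.columns:
            raise ValueError(f"missing per-cell stat '{col}'")
        vals = stats[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError(f"non-finite or negative values in '{col}'")
    mito = stats["mito_frac"].to_numpy(dtype=float)
    umi = stats["umi"].to_numpy(dtype=float)
    genes = stats["genes"].to_numpy(dtype=float)
    fail_mito = mito > thresholds.max_mito_fraction
    fail_low_umi = umi < thresholds.min_umi
    fail_high_umi = umi > thresholds.max_umi
    fail_genes = genes > thresholds.max_genes
    removed_mask = fail_mito | fail_low_umi | fail_high_umi | fail_genes
    counts = {
        "n_input": len(stats),
        "n_removed": int(removed_mask.sum()),
        "n_kept": int((~removed_mask).sum()),
        "fail_mito": int(fail_mito.sum()),
        "fail_low_umi": int(fail_low_umi.sum()),
        "fail_high_umi": int(fail_high_umi.sum()),
        "fail_genes": int(fail_genes.sum()),
    }
    return (
        stats[~removed_mask].reset_index(drop=True),
        stats[removed_mask].reset_index(drop=True),
        counts,
    )
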