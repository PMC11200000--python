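"""CNV detection from ATAC tile coverage and CNV masking of DMRs.

Copy-number change shows up in single-cell ATAC data as a coherent
coverage shift over large tile windows, which confounds accessibility
clustering.  This module derives per-donor copy-number segments from
depth-normalized tile coverage log-ratios via CBS (shared implementation
with the methylation pipeline), keeps only calls corroborated by an
external (panel-sequencing) CNV profile, and removes any DMR overlapping
such a region, yielding the CNV-free DMR feature set used for
epigenotype clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .cbs import CbsParams, segment_track
from .regions import as_region_frame, merge_regions, overlaps_any, reciprocal_overlap_fraction
from .synth import CellMatrix


def coverage_log_ratio(
    matrix: CellMatrix,
    group_labels: pd.Series,
    group: str,
    reference: str,
    pseudocount: float = 0.01,
    center: bool = True,
) -> pd.DataFrame:
    """Per-tile log2 coverage ratio of ``group`` cells vs ``reference`` cells.

    Each cell's counts are first normalized to mean 1 per tile (depth
    removal), so only coverage *composition* differences remain.  The
    pseudocount is on that mean-1 scale.  With ``center`` (default) the
    track is median-centered: per-cell normalization in a genome with
    substantial gains or losses shifts the baseline of all other tiles,
    and the median restores neutral tiles to ~0 as long as fewer than
    half of the tiles are copy-altered.
    """
    labels = group_labels.reindex(matrix.cells["cell_id"]).to_numpy()
    g_idx = np.flatnonzero(labels == group)
    r_idx = np.flatnonzero(labels == reference)
    if g_idx.size == 0 or r_idx.size == 0:
        raise ValueError(f"empty group ({group}: {g_idx.size}, {reference}: {r_idx.size})")
    counts = matrix.counts.tocsc()
    n_regions = counts.shape[0]

    def _profile(idx):
        sub = counts[:, idx]
        depth = np.asarray(sub.sum(axis=0)).ravel().astype(float)
        depth[depth == 0] = 1.0
        norm = sub @ sparse.diags(n_regions / depth)
        return np.asarray(norm.mean(axis=1)).ravel()

    g = _profile(g_idx)
    r = _profile(r_idx)
    track = matrix.regions[["chrom", "start", "end"]].copy()
    lr = np.log2((g + pseudocount) / (r + pseudocount))
    if center:
        lr = lr - np.median(lr)
    track["log_ratio"] = lr
    track["group"] = group
    return track


def call_cnv_segments(
    track: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_tiles: int = 3,
    state_threshold: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """CBS on the log-ratio track; segments with |mean| > threshold are
    labeled gain/loss, the rest neutral."""
    params = CbsParams(alpha=alpha, n_perm=n_perm, min_seg=min_tiles)
    seg = segment_track(track, "log_ratio", params, seed=seed)
    seg = seg.rename(columns={"mean": "log_ratio"})
    seg["state"] = np.where(
        seg["log_ratio"] > state_threshold,
        "gain",
        np.where(seg["log_ratio"] < -state_threshold, "loss", "neutral"),
    )
    return seg


def intersect_true_cnv(
    atac_profile: pd.DataFrame,
    panel_profile: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Keep non-neutral ATAC segments reciprocally overlapping (>= fraction)
    a same-direction panel segment; return the merged region set."""
    if "donor" in atac_profile.columns and "donor" in panel_profile.columns:
        da = set(atac_profile["donor"].unique())
        dp = set(panel_profile["donor"].unique())
        if da and dp and da != dp:
            raise ValueError(f"donor mismatch: {da} vs {dp}")
    atac = atac_profile[atac_profile["state"].isin(["gain", "loss"])]
    panel = panel_profile[panel_profile["state"].isin(["gain", "loss"])]
    kept = []
    for a in atac.itertuples(index=False):
        a_iv = (a.chrom, a.start, a.end)
        for p in panel.itertuples(index=False):
            if p.state != a.state:
                continue
            if reciprocal_overlap_fraction(a_iv, (p.chrom, p.start, p.end)) >= min_overlap_fraction:
                kept.append({"chrom": a.chrom, "start": a.start, "end": a.end})
                break
    if not kept:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_regions(pd.DataFrame(kept))


def mask_regions(dmrs: pd.DataFrame, cnv: pd.DataFrame) -> pd.DataFrame:
    """Remove every DMR with ANY base of overlap with a CNV region.

    Survivors pass through unchanged (no trimming): a partially
    CNV-confounded feature is unsafe for epigenotype clustering.
    """
    dmrs = as_region_frame(dmrs)
    if len(dmrs) == 0 or len(cnv) == 0:
        return dmrs.reset_index(drop=True)
    hit = overlaps_any(dmrs, cnv)
    return dmrs[~hit].reset_index(drop=True)
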