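"""DMR calling from per-CpG beta values.

The pipeline proceeds in five stages:

1. ``call_dml`` — per-locus Welch t-test (case vs control) plus an
   absolute beta-difference cutoff yields differentially methylated loci.
2. ``merge_dml`` — DML within ``max_gap_bp`` of each other on the same
   chromosome are merged into initial DMR candidates.
3. ``test_seed_dmrs`` — a candidate whose per-sample mean beta (over its
   loci) again separates the groups at p < threshold becomes a *seed*.
4. ``segment_delta_beta`` + ``cluster_segments`` — the genome-wide
   case-minus-control beta-difference track is segmented by CBS and the
   segment means are k-means clustered (default k=3: hypo/null/hyper).
5. ``select_true_dmrs`` — every segment of any k-means cluster that has
   at least one segment fully encompassing a seed is emitted as a final
   DMR call.

Defaults: p < 0.01, |delta beta| > 0.1, merge gap <= 100 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .cbs import CbsParams, segment_track
from .regions import contains
from .synth import BetaMatrix

DML_COLS = ["chrom", "pos", "p_value", "delta_beta", "direction"]


def _group_values(beta: BetaMatrix):
    case = beta.values[:, beta.case_mask]
    ctrl = beta.values[:, ~beta.case_mask]
    return case, ctrl


def call_dml(
    beta: BetaMatrix,
    p_threshold: float = 0.01,
    delta_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-locus differential test.

    A locus is a DML iff the two-sided Welch t-test between groups gives
    p < ``p_threshold`` AND |case mean - control mean| > ``delta_threshold``.
    Loci with fewer than two non-missing observations in either group are
    skipped (counted in a warning).
    """
    case, ctrl = _group_values(beta)
    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    ok = (n_case >= 2) & (n_ctrl >= 2)
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} loci skipped: <2 observations in a group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False, nan_policy="omit")
        delta = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)
    is_dml = ok & np.isfinite(p) & (p < p_threshold) & (np.abs(delta) > delta_threshold)
    out = beta.loci.loc[is_dml, ["chrom", "pos"]].copy()
    out["p_value"] = p[is_dml]
    out["delta_beta"] = delta[is_dml]
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    out["locus_idx"] = np.flatnonzero(is_dml)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def merge_dml(dml: pd.DataFrame, max_gap_bp: int = 100) -> pd.DataFrame:
    """Merge runs of same-chromosome DML with successive gaps <= ``max_gap_bp``.

    Candidate regions span the first to last merged locus, half-open
    (+1 on the end).  Input must be coordinate-sorted.
    """
    if len(dml) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_loci", "first_idx", "last_idx"]
        )
    rows = []
    cur = None  # [chrom, first_pos, last_pos, n, first_idx, last_idx]
    for rec in dml.itertuples(index=False):
        if cur is not None and rec.chrom == cur[0] and rec.pos - cur[2] <= max_gap_bp:
            cur[2] = rec.pos
            cur[3] += 1
            cur[5] = rec.locus_idx
        else:
            if cur is not None:
                rows.append(cur)
            cur = [rec.chrom, rec.pos, rec.pos, 1, rec.locus_idx, rec.locus_idx]
    rows.append(cur)
    return pd.DataFrame(
        [
            {
                "chrom": c,
                "start": int(s),
                "end": int(e) + 1,
                "n_loci": n,
                "first_idx": int(fi),
                "last_idx": int(li),
            }
            for c, s, e, n, fi, li in rows
        ]
    )


def test_seed_dmrs(
    beta: BetaMatrix, candidates: pd.DataFrame, p_threshold: float = 0.01
) -> pd.DataFrame:
    """T-test each candidate's per-sample mean beta; ``is_seed`` = p < threshold."""
    if len(candidates) and (candidates["n_loci"] <= 0).any():
        raise ValueError("candidate with zero loci: pipeline inconsistency")
    out = candidates.copy()
    seeds, pvals, means = [], [], []
    case_mask = beta.case_mask
    chrom_arr = beta.loci["chrom"].to_numpy()
    pos_arr = beta.loci["pos"].to_numpy()
    for rec in candidates.itertuples(index=False):
        sel = (chrom_arr == rec.chrom) & (pos_arr >= rec.start) & (pos_arr < rec.end)
        if not sel.any():
            raise ValueError("candidate encompasses no loci")
        per_sample = np.nanmean(beta.values[sel, :], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(
                per_sample[case_mask], per_sample[~case_mask], equal_var=False
            )
        p = float(p) if np.isfinite(p) else 1.0
        pvals.append(p)
        seeds.append(p < p_threshold)
        means.append(
            float(np.mean(per_sample[case_mask]) - np.mean(per_sample[~case_mask]))
        )
    out["p_value"] = pvals
    out["mean_delta_beta"] = means
    out["is_seed"] = seeds
    return out


def delta_track(beta: BetaMatrix) -> pd.DataFrame:
    """Per-locus case-minus-control mean beta over ALL tested loci."""
    case, ctrl = _group_values(beta)
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)
    track = beta.loci.copy()
    track["delta_beta"] = delta
    return track[np.isfinite(delta)].reset_index(drop=True)


def segment_delta_beta(
    track: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_loci: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """CBS-segment the beta-difference track (see :mod:`epibridge.cbs`)."""
    params = CbsParams(alpha=alpha, n_perm=n_perm, min_seg=min_loci)
    seg = segment_track(track, "delta_beta", params, seed=seed)
    return seg.rename(columns={"mean": "mean_delta_beta"})


def cluster_segments(segments: pd.DataFrame, k: int = 3, seed: int = 0) -> pd.DataFrame:
    """1-D k-means on segment mean delta beta; labels ordered by centroid."""
    if k > len(segments):
        raise ValueError(f"k={k} exceeds number of segments ({len(segments)})")
    out = segments.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    x = out["mean_delta_beta"].to_numpy()[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    out["kmeans_cluster"] = relabel[km.labels_]
    return out


def select_true_dmrs(segments: pd.DataFrame, seeds: pd.DataFrame) -> pd.DataFrame:
    """Final DMRs: all segments of every cluster with >=1 segment fully
    encompassing >=1 seed DMR (half-open interval containment)."""
    seeds = seeds[seeds["is_seed"]] if "is_seed" in seeds.columns else seeds
    if len(seeds) == 0:
        warnings.warn("no seed DMRs: empty final DMR set")
        return segments.iloc[0:0].assign(provenance="segment-cluster")
    selected = set()
    seed_ivs = [(r.chrom, r.start, r.end) for r in seeds.itertuples(index=False)]
    for rec in segments.itertuples(index=False):
        seg_iv = (rec.chrom, rec.start, rec.end)
        if any(contains(seg_iv, s) for s in seed_ivs):
            selected.add(rec.kmeans_cluster)
    out = segments[segments["kmeans_cluster"].isin(selected)].copy()
    out["provenance"] = "segment-cluster"
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


@dataclass
class DmrParams:
    p_threshold: float = 0.01
    delta_threshold: float = 0.1
    max_gap_bp: int = 100
    seed_p_threshold: float = 0.01
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    min_loci: int = 3
    k: int = 3
    seed: int = 0


@dataclass
class DmrResult:
    dml: pd.DataFrame
    candidates: pd.DataFrame
    seeds: pd.DataFrame
    segments: pd.DataFrame
    dmrs: pd.DataFrame


def call_dmrs(beta: BetaMatrix, params: DmrParams | None = None) -> DmrResult:
    """End-to-end DMR calling with the five-stage procedure."""
    params = params or DmrParams()
    dml = call_dml(beta, params.p_threshold, params.delta_threshold)
    candidates = merge_dml(dml, params.max_gap_bp)
    if len(candidates):
        seeds = test_seed_dmrs(beta, candidates, params.seed_p_threshold)
    else:
        seeds = candidates.assign(p_value=[], mean_delta_beta=[], is_seed=[])
    track = delta_track(beta)
    segments = segment_delta_beta(
        track,
        alpha=params.cbs_alpha,
        n_perm=params.cbs_n_perm,
        min_loci=params.min_loci,
        seed=params.seed,
    )
    k = min(params.k, len(segments))
    segments = cluster_segments(segments, k=k, seed=params.seed)
    dmrs = select_true_dmrs(segments, seeds)
    return DmrResult(dml=dml, candidates=candidates, seeds=seeds, segments=segments, dmrs=dmrs)
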