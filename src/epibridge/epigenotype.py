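"""Epigenotype clustering: TF-IDF + LSI on accessibility over CNV-free DMRs.

An *epigenotype* is a cluster of single cells defined by chromatin
accessibility over copy-number-free differentially methylated regions,
rather than by transcriptome.  The embedding is the standard scATAC
latent semantic indexing: binarize (accessibility presence), weight by
log inverse document frequency, L2-normalize per cell, truncated SVD.
Components strongly correlated with per-cell sequencing depth are
flagged and excluded from clustering distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.metrics import silhouette_score

from .entropy import shannon_entropy
from .synth import CellMatrix


@dataclass
class Embedding:
    """LSI embedding of cells with per-component depth correlation."""

    cells: pd.Index
    coords: np.ndarray  # cells x d
    depth_correlation: np.ndarray  # per component, in [-1, 1]
    retained: np.ndarray  # boolean per component

    @property
    def retained_coords(self) -> np.ndarray:
        return self.coords[:, self.retained]


def tfidf_lsi(
    matrix: CellMatrix,
    d: int = 30,
    drop_depth_corr: float = 0.9,
    binarize: bool = True,
    seed: int = 0,
) -> Embedding:
    """TF-IDF weighting followed by truncated SVD.

    With ``binarize`` (default), term frequency is presence/absence per
    region, making the embedding invariant to per-cell depth scaling;
    otherwise log1p counts are used.  Components whose absolute Pearson
    correlation with log total counts exceeds ``drop_depth_corr`` are
    flagged as depth components and dropped from ``retained``.
    """
    counts = matrix.counts.tocsc()
    n_regions, n_cells = counts.shape
    if n_cells == 0 or n_regions == 0:
        raise ValueError("empty matrix")
    if d >= min(n_regions, n_cells):
        raise ValueError(f"d={d} must be < min(n_regions, n_cells)")
    depth = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if (depth == 0).any():
        raise ValueError("all-zero cells present; run QC first")
    X = counts.T.tocsr().astype(float)  # cells x regions
    if binarize:
        X.data = np.ones_like(X.data)
    else:
        X.data = np.log1p(X.data)
    # term frequency: per-cell row normalization
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    X = sparse.diags(1.0 / row_sums) @ X
    df = np.asarray((counts > 0).sum(axis=1)).ravel().astype(float)
    idf = np.log(1.0 + n_cells / (1.0 + df))
    X = X @ sparse.diags(idf)
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    X = sparse.diags(1.0 / norms) @ X
    # arpack: exact partial SVD, invariant to cell order (up to fixed signs)
    svd = TruncatedSVD(n_components=d, random_state=seed, algorithm="arpack")
    coords = svd.fit_transform(X)
    logd = np.log(depth)
    corr = np.zeros(d)
    for c in range(d):
        v = coords[:, c]
        if v.std() == 0 or logd.std() == 0:
            corr[c] = 0.0
        else:
            corr[c] = float(np.corrcoef(v, logd)[0, 1])
    retained = np.abs(corr) <= drop_depth_corr
    if not retained.any():
        retained = np.ones(d, dtype=bool)
    return Embedding(
        cells=pd.Index(matrix.cells["cell_id"]),
        coords=coords,
        depth_correlation=corr,
        retained=retained,
    )


def cluster_epigenotypes(
    embedding: Embedding,
    k: int | str = "auto",
    seed: int = 0,
    k_range: tuple[int, int] = (2, 20),
) -> pd.Series:
    """Centroid clustering of the retained LSI components.

    ``k='auto'`` selects k within ``k_range`` by mean silhouette score.
    Returns a per-cell epigenotype label Series.
    """
    X = embedding.retained_coords
    n = X.shape[0]
    if isinstance(k, str):
        best_k, best_s = None, -np.inf
        for kk in range(k_range[0], min(k_range[1], n - 1) + 1):
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(X)
            s = silhouette_score(X, km.labels_)
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells ({n})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    # stable labels: order clusters by size (desc), then first occurrence
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = pd.Series(
        [f"E{relabel[l]}" for l in km.labels_], index=embedding.cells, name="epigenotype"
    )
    return labels


def donor_diversity(
    assignment: pd.Series, donors: pd.Series, normalized: bool = False
) -> pd.Series:
    """Per-cluster Shannon entropy of donor composition.

    High entropy: the cluster is shared across donors; zero: donor-private
    (the hallmark of CNV-driven or patient-specific states).
    """
    donors = donors.reindex(assignment.index)
    if donors.isna().any():
        raise ValueError("every cell needs a donor label")
    out = {}
    for cluster, sub in donors.groupby(assignment):
        out[cluster] = shannon_entropy(sub.value_counts().to_numpy(), normalized=normalized)
    return pd.Series(out, name="donor_diversity").sort_index()


def within_donor_heterogeneity(
    assignment: pd.Series, donors: pd.Series, normalized: bool = False
) -> pd.Series:
    """Per-donor Shannon entropy of cluster composition (roles swapped)."""
    return donor_diversity(donors, assignment, normalized=normalized).rename(
        "within_donor_heterogeneity"
    )
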