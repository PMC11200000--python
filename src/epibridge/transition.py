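"""Cross-modality transition graph and plasticity entropy.

Given a joint-cluster table (cells from both modalities assigned to
shared co-embedding clusters), the frequency matrix F holds, per source
cluster (RNA cell type or ATAC epigenotype), the fraction of its cells
in each joint cluster.  The adjacency A = F F^T then measures
co-occupancy between source clusters; denoising keeps only the top
quantile of off-diagonal weights.  Removing the ATAC (epigenotype)
nodes from the resulting graph reveals how much of the connectivity
between transcriptional states is carried by bridging epigenotypes.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .entropy import shannon_entropy

JOINT_COLS = ["cell_id", "modality", "source_cluster", "joint_cluster"]


def _validate_joint(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in JOINT_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"joint-cluster table missing columns: {missing}")
    if table["cell_id"].duplicated().any():
        raise ValueError("cells must appear exactly once in the joint table")
    return table


def frequency_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized (source cluster x joint cluster) occupancy fractions.

    Rows are indexed by (modality, source_cluster) so RNA and ATAC
    clusters with identical names stay distinct; every row sums to 1.
    """
    table = _validate_joint(table)
    counts = (
        table.groupby(["modality", "source_cluster", "joint_cluster"], sort=True)
        .size()
        .unstack("joint_cluster", fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty source cluster")
    return counts.div(totals, axis=0)


def adjacency(F: pd.DataFrame) -> pd.DataFrame:
    """A = F F^T; A_ij = sum_g F_ig F_jg (symmetric, PSD).

    The diagonal is retained in the raw matrix; denoising ignores it.
    """
    A = F.to_numpy() @ F.to_numpy().T
    return pd.DataFrame(A, index=F.index, columns=F.index)


def denoise_top_quantile(A: pd.DataFrame, q: float = 0.01) -> nx.Graph:
    """Keep edges whose weight reaches the top-``q`` quantile.

    The threshold is the (1-q) quantile of the off-diagonal
    upper-triangle values (zeros included in the quantile); edges with
    w >= threshold are kept, ties at the threshold included.  A zero
    weight is never an edge: it means the two clusters share no joint
    cluster at all.  Node attribute ``modality`` is carried over; the
    graph has no self-loops.
    """
    M = A.to_numpy()
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    n = M.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = M[iu, ju]
    if vals.size == 0:
        thr = 0.0
    elif np.allclose(vals, vals[0]):
        warnings.warn("all off-diagonal weights equal: degenerate threshold, keeping all edges")
        thr = vals[0]
    else:
        thr = float(np.quantile(vals, 1.0 - q))
    G = nx.Graph()
    for node in A.index:
        modality = node[0] if isinstance(node, tuple) else None
        G.add_node(node, modality=modality)
    for i, j, w in zip(iu, ju, vals):
        if w > 0 and w >= thr:
            G.add_edge(A.index[i], A.index[j], weight=float(w))
    return G


def bridging_analysis(graph: nx.Graph) -> dict:
    """Connectivity report before/after removing all ATAC nodes.

    Fragmentation of the RNA-only graph (more components, isolated
    nodes) indicates that epigenotype nodes bridge transcriptional
    states.
    """
    degrees = dict(graph.degree())
    comps_full = list(nx.connected_components(graph))
    atac_nodes = [n for n, d in graph.nodes(data=True) if d.get("modality") == "ATAC"]
    rna_graph = graph.copy()
    rna_graph.remove_nodes_from(atac_nodes)
    comps_rna = list(nx.connected_components(rna_graph))
    isolated = [n for n in rna_graph.nodes if rna_graph.degree(n) == 0]
    def _name(node):
        return ":".join(map(str, node)) if isinstance(node, tuple) else str(node)

    degree_ranking = sorted(
        ((_name(n), d) for n, d in degrees.items()), key=lambda kv: (-kv[1], kv[0])
    )
    return {
        "n_components_full": len(comps_full),
        "n_components_rna_only": len(comps_rna),
        "n_isolated_rna_nodes": len(isolated),
        "degrees": {_name(n): d for n, d in degrees.items()},
        "degree_ranking": degree_ranking,
        "atac_nodes_removed": [_name(n) for n in atac_nodes],
        "components_full": [sorted(map(_name, c)) for c in comps_full],
        "components_rna_only": [sorted(map(_name, c)) for c in comps_rna],
    }


def match_modalities(
    atac_coords: pd.DataFrame, rna_coords: pd.DataFrame, rna_labels: pd.Series
) -> pd.DataFrame:
    """Nearest-RNA-cell match for every ATAC cell in a shared space.

    Both coordinate frames are indexed by cell ID.  Euclidean distance;
    exact ties resolved toward the lowest RNA cell ID.
    """
    if len(rna_coords) == 0:
        raise ValueError("empty RNA set")
    rna_coords = rna_coords.sort_index(kind="stable")
    R = rna_coords.to_numpy(dtype=float)
    A = atac_coords.to_numpy(dtype=float)
    rows = []
    block = 2048
    for s in range(0, A.shape[0], block):
        chunk = A[s : s + block]
        d2 = ((chunk[:, None, :] - R[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)  # first index wins ties; IDs sorted
        for off, r in enumerate(nearest):
            rows.append(
                {
                    "atac_cell": atac_coords.index[s + off],
                    "matched_rna_cell": rna_coords.index[r],
                    "matched_rna_cluster": rna_labels.loc[rna_coords.index[r]],
                }
            )
    return pd.DataFrame(rows)


def plasticity_entropy(matches: pd.DataFrame, atac_labels: pd.Series) -> pd.Series:
    """Shannon entropy of the matched-RNA-cluster distribution per epigenotype.

    High entropy = the epigenotype realizes many transcriptional states
    (high plasticity).  Epigenotypes with no matched cell get NaN.
    """
    labels = atac_labels.reindex(matches["atac_cell"])
    if labels.isna().any():
        raise ValueError("matched ATAC cell without epigenotype label")
    out = {}
    for eg, sub in matches.groupby(labels.to_numpy()):
        out[eg] = shannon_entropy(sub["matched_rna_cluster"].value_counts().to_numpy())
    result = pd.Series(out, name="plasticity_entropy", dtype=float)
    return result.reindex(sorted(set(atac_labels))).sort_index()


def matches_from_joint(table: pd.DataFrame) -> pd.DataFrame:
    """Co-membership matcher: each ATAC cell is matched to the majority
    RNA source cluster of its joint cluster (ties to the lexicographically
    smallest; clusters without RNA cells yield no match)."""
    table = _validate_joint(table)
    rna = table[table["modality"] == "RNA"]
    majority = {}
    for j, sub in rna.groupby("joint_cluster"):
        counts = sub["source_cluster"].value_counts()
        top = counts[counts == counts.max()].index.min()
        majority[j] = top
    atac = table[table["modality"] == "ATAC"]
    matched = atac[atac["joint_cluster"].isin(majority)]
    return pd.DataFrame(
        {
            "atac_cell": matched["cell_id"].to_numpy(),
            "matched_rna_cell": pd.NA,
            "matched_rna_cluster": [majority[j] for j in matched["joint_cluster"]],
        }
    )
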