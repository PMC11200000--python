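"""TCR clone definition and clonal-expansion classification.

A clone is the set of cells from one donor expressing exactly the same
chain combination: identical locus / V / J / C gene usage and identical
CDR3 nucleotide sequence for every chain (alpha and beta, if present).
Cells carrying three or more assembled chains are removed as likely
multiplets before clone counting.

Expansion labels per clone (counts per sample within the donor):

- ``global``  — observed > 2 times in >= 2 samples;
- ``local``   — observed > 2 times in exactly one sample and < 2 times
  (i.e. <= 1) in every other sample;
- ``diffuse`` — donor total > 2 but neither rule applies (e.g. one
  sample > 2 and another exactly 2); kept as an explicit category so
  the printed local/global definitions are applied verbatim while no
  clone is left unlabeled;
- ``singlet`` — donor total <= 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .entropy import shannon_entropy

CELL_COLS = ["barcode", "donor", "sample", "chain", "v_gene", "j_gene", "c_gene", "cdr3_nt"]

LABELS = ("singlet", "local", "global", "diffuse")


def filter_multiplets(cells: pd.DataFrame, max_chains: int = 2):
    """Drop cells (barcodes) with >= 3 assembled chains.

    Returns ``(kept, n_removed)`` where ``n_removed`` counts removed cells.
    """
    if len(cells) == 0:
        return cells.copy(), 0
    if (cells["cdr3_nt"].astype(str).str.len() == 0).any():
        raise ValueError("chain with empty CDR3 sequence")
    chain_counts = cells.groupby(["donor", "barcode"])["chain"].transform("size")
    keep = chain_counts <= max_chains
    n_removed = int(cells.loc[~keep, ["donor", "barcode"]].drop_duplicates().shape[0])
    return cells[keep].reset_index(drop=True), n_removed


def _clone_key(chains: pd.DataFrame) -> str:
    parts = sorted(
        f"{r.chain}|{r.v_gene}|{r.j_gene}|{r.c_gene}|{str(r.cdr3_nt).upper()}"
        for r in chains.itertuples(index=False)
    )
    return ";".join(parts)


def define_clones(cells: pd.DataFrame) -> pd.DataFrame:
    """Group filtered cells into clones; long-format per-sample counts.

    Returns a frame with columns (donor, clone_key, sample, count);
    identical chain sets in different donors are distinct clones.
    """
    if len(cells) == 0:
        return pd.DataFrame(columns=["donor", "clone_key", "sample", "count"])
    keyed = (
        cells.groupby(["donor", "barcode", "sample"], sort=False)[
            ["chain", "v_gene", "j_gene", "c_gene", "cdr3_nt"]
        ]
        .apply(_clone_key)
        .rename("clone_key")
        .reset_index()
    )
    out = (
        keyed.groupby(["donor", "clone_key", "sample"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def _label_from_counts(counts: np.ndarray) -> str:
    """Expansion label from one clone's per-sample counts (0s allowed)."""
    counts = np.asarray(counts, dtype=int)
    total = counts.sum()
    over = counts > 2
    if over.sum() >= 2:
        return "global"
    if over.sum() == 1 and (counts[~over] <= 1).all():
        return "local"
    if total > 2:
        return "diffuse"
    return "singlet"


def classify_expansion(clone_table: pd.DataFrame) -> pd.DataFrame:
    """Per-clone expansion label from the long-format clone table."""
    rows = []
    for (donor, key), sub in clone_table.groupby(["donor", "clone_key"], sort=True):
        counts = sub["count"].to_numpy()
        rows.append(
            {
                "donor": donor,
                "clone_key": key,
                "total": int(counts.sum()),
                "label": _label_from_counts(counts),
            }
        )
    return pd.DataFrame(rows, columns=["donor", "clone_key", "total", "label"])


def clonotype_diversity(
    clone_table: pd.DataFrame, by: str = "donor", normalized: bool = False
) -> pd.Series:
    """Shannon entropy of clone-size fractions within each donor or sample."""
    if by not in ("donor", "sample"):
        raise ValueError("by must be 'donor' or 'sample'")
    if len(clone_table) == 0:
        raise ValueError("empty clone table")
    out = {}
    for scope, sub in clone_table.groupby(by, sort=True):
        sizes = sub.groupby("clone_key")["count"].sum().to_numpy()
        out[scope] = shannon_entropy(sizes, normalized=normalized)
    return pd.Series(out, name="clonotype_diversity")


def expansion_prevalence(labels: pd.DataFrame, donor_stages: pd.DataFrame) -> pd.Series:
    """Per-stage fraction of donors carrying >= 1 locally expanded clone.

    ``donor_stages`` needs columns (donor, stage) covering every donor.
    """
    stages = donor_stages.set_index("donor")["stage"]
    donors_with_local = set(labels.loc[labels["label"] == "local", "donor"])
    missing = set(labels["donor"]) - set(stages.index)
    if missing:
        raise ValueError(f"donors without stage: {sorted(missing)}")
    out = {}
    for stage, sub in stages.groupby(stages):
        donors = sub.index
        out[stage] = sum(d in donors_with_local for d in donors) / len(donors)
    return pd.Series(out, name="local_expansion_prevalence")
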