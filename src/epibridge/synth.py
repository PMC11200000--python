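"""Synthetic data generators with planted ground truth.

Every downstream stage of the package (DMR calling, CNV masking,
epigenotype clustering, the transition graph, TCR clonality) is
exercisable on data from this module, with the planted truth returned
alongside so recovery is directly checkable.  Each generator is a pure
function of its config, including the seed; all randomness flows from a
single ``numpy.random.Generator`` per call.

What is emulated (and what is not) is laid out in docs/methods.md: the
generators reproduce the *statistical structure* the pipeline consumes —
two-group beta matrices with contiguous shifted windows, epigenotype- and
CNV-structured Poisson accessibility counts, joint-cluster tables with
bridging states, long-tailed clonotype tables — not read-level data or
real genome annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# methylation


@dataclass(frozen=True)
class MethylSimConfig:
    """Two-group beta matrix with planted hypermethylated windows.

    ``delta_beta`` is the case-minus-control shift planted on each DMR
    window; in-window baselines are rescaled into [0.05, 0.95-delta] so
    the shift survives clipping to [0, 1].  ``read_noise_sd`` is the
    per-observation Gaussian noise, matching a high-coverage targeted
    bisulfite capture regime.
    """

    n_loci: int = 50_000
    n_chroms: int = 20
    samples_per_group: int = 10
    n_dmrs: int = 20
    dmr_width_loci: tuple[int, int] = (10, 30)
    delta_beta: float = 0.3
    baseline_beta_params: tuple[float, float] = (0.8, 0.8)
    read_noise_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.delta_beta <= 0.9):
            raise ConfigError("delta_beta must be in [0, 0.9]")
        if self.dmr_width_loci[0] < 1 or self.dmr_width_loci[0] > self.dmr_width_loci[1]:
            raise ConfigError("invalid dmr_width_loci range")
        if self.n_dmrs * self.dmr_width_loci[1] >= self.n_loci:
            raise ConfigError("planted DMRs would not fit in n_loci")
        if self.samples_per_group < 2:
            raise ConfigError("need >=2 samples per group")
        if min(self.baseline_beta_params) <= 0:
            raise ConfigError("baseline beta shape parameters must be positive")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd must be nonnegative")


@dataclass
class BetaMatrix:
    """Per-CpG beta values for case/control samples.

    ``loci``: DataFrame (chrom, pos), position strictly increasing per
    chromosome; ``values``: loci x samples array in [0, 1] (NaN =
    missing); ``group``: per-sample label, 'case' or 'control'.
    """

    loci: pd.DataFrame
    values: np.ndarray
    samples: list[str]
    group: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.loci), len(self.samples)):
            raise ValueError("values shape does not match loci x samples")
        for lab in ("case", "control"):
            if (self.group == lab).sum() < 2:
                raise ValueError(f"need >=2 '{lab}' samples")

    @property
    def case_mask(self) -> np.ndarray:
        return self.group == "case"


def simulate_methylation(config: MethylSimConfig):
    """Return (BetaMatrix, true-DMR region frame)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    per_chrom = np.full(config.n_chroms, config.n_loci // config.n_chroms)
    per_chrom[: config.n_loci % config.n_chroms] += 1

    chroms, positions = [], []
    for c, n in enumerate(per_chrom):
        gaps = rng.integers(15, 150, size=n)
        pos = 1000 + np.cumsum(gaps)
        chroms.append(np.full(n, f"chr{c + 1}"))
        positions.append(pos)
    loci = pd.DataFrame(
        {"chrom": np.concatenate(chroms), "pos": np.concatenate(positions)}
    )
    chrom_offsets = np.concatenate(([0], np.cumsum(per_chrom)))

    # place non-overlapping windows, round-robin over chromosomes
    wlo, whi = config.dmr_width_loci
    windows: list[tuple[int, int]] = []  # global locus index ranges
    for d in range(config.n_dmrs):
        width = int(rng.integers(wlo, whi + 1))
        placed = False
        for _ in range(1000):
            c = int(rng.integers(0, config.n_chroms))
            lo, hi = chrom_offsets[c], chrom_offsets[c + 1]
            if hi - lo <= width:
                continue
            s = int(rng.integers(lo, hi - width))
            if all(e <= s or s + width <= b for b, e in windows):
                windows.append((s, s + width))
                placed = True
                break
        if not placed:
            raise ConfigError("could not place non-overlapping DMR windows")
    windows.sort()

    a, b = config.baseline_beta_params
    baseline = rng.beta(a, b, size=config.n_loci)
    for s, e in windows:
        # keep head-room for the planted shift
        baseline[s:e] = 0.05 + baseline[s:e] * (0.90 - config.delta_beta)

    n_samples = 2 * config.samples_per_group
    group = np.array(
        ["case"] * config.samples_per_group + ["control"] * config.samples_per_group
    )
    values = baseline[:, None] + rng.normal(
        0.0, config.read_noise_sd, size=(config.n_loci, n_samples)
    )
    case_cols = group == "case"
    for s, e in windows:
        values[s:e, :][:, case_cols] += config.delta_beta
    np.clip(values, 0.0, 1.0, out=values)

    samples = [f"case_{i}" for i in range(config.samples_per_group)] + [
        f"ctrl_{i}" for i in range(config.samples_per_group)
    ]
    beta = BetaMatrix(loci=loci, values=values, samples=samples, group=group)

    truth = pd.DataFrame(
        {
            "chrom": [loci["chrom"].iloc[s] for s, _ in windows],
            "start": [int(loci["pos"].iloc[s]) for s, _ in windows],
            "end": [int(loci["pos"].iloc[e - 1]) + 1 for _, e in windows],
            "first_locus": [s for s, _ in windows],
            "last_locus": [e for _, e in windows],
        }
    )
    return beta, truth


# ---------------------------------------------------------------------------
# scATAC


@dataclass(frozen=True)
class AtacSimConfig:
    """Epigenotype-structured accessibility counts with donor CNV.

    Donor 0 carries no CNV and serves as the log-ratio reference.  Each
    other donor gets ``cnv_segments_per_donor`` contiguous tile segments
    whose Poisson rates are multiplied by ``cnv_fold`` (gain) or
    1/``cnv_fold`` (loss).  Each epigenotype elevates its own disjoint
    signature region set by ``signal_fold``.
    """

    n_cells: int = 1200
    n_regions: int = 2500
    n_epigenotypes: int = 4
    n_donors: int = 5
    signal_fold: float = 3.0
    cnv_segments_per_donor: int = 6
    cnv_fold: float = 4.0
    depth_mean: float = 1000.0
    bridging_map: dict | None = None
    n_chroms: int = 8
    tile_width: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if self.n_epigenotypes > self.n_cells:
            raise ConfigError("more epigenotypes than cells")
        if self.n_epigenotypes < 1 or self.n_donors < 1:
            raise ConfigError("need >=1 epigenotype and donor")
        if self.signal_fold <= 0 or self.cnv_fold <= 0 or self.depth_mean <= 0:
            raise ConfigError("fold and depth parameters must be positive")
        if self.bridging_map is not None:
            for e, ps in self.bridging_map.items():
                if len(ps) == 0:
                    raise ConfigError(f"epigenotype {e} maps to no phenotype")


@dataclass
class CellMatrix:
    """Sparse region x cell counts with region and cell metadata."""

    regions: pd.DataFrame  # chrom, start, end
    cells: pd.DataFrame  # cell_id, donor, sample, tissue, stage
    counts: sparse.csr_matrix  # regions x cells

    def __post_init__(self):
        if self.counts.shape != (len(self.regions), len(self.cells)):
            raise ValueError("counts shape mismatch")


def simulate_atac(config: AtacSimConfig):
    """Return (CellMatrix, epigenotype labels, CNV profiles, signature regions)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, N, K, D = config.n_regions, config.n_cells, config.n_epigenotypes, config.n_donors

    per_chrom = np.full(config.n_chroms, R // config.n_chroms)
    per_chrom[: R % config.n_chroms] += 1
    rc, rs = [], []
    for c, n in enumerate(per_chrom):
        rc.append(np.full(n, f"chr{c + 1}"))
        rs.append(np.arange(n) * config.tile_width)
    regions = pd.DataFrame(
        {
            "chrom": np.concatenate(rc),
            "start": np.concatenate(rs),
        }
    )
    regions["end"] = regions["start"] + config.tile_width
    chrom_offsets = np.concatenate(([0], np.cumsum(per_chrom)))

    epigenotype = rng.integers(0, K, size=N)
    donor = rng.integers(0, D, size=N)

    # epigenotype signature weights on disjoint scattered region sets
    sig_per_eg = R // (K + 1)
    shuffled = rng.permutation(R)
    W = np.ones((R, K))
    sig_rows = []
    for e in range(K):
        idx = shuffled[e * sig_per_eg : (e + 1) * sig_per_eg]
        W[idx, e] = config.signal_fold
        for r in idx:
            sig_rows.append(
                {
                    "chrom": regions["chrom"].iloc[r],
                    "start": int(regions["start"].iloc[r]),
                    "end": int(regions["end"].iloc[r]),
                    "epigenotype": f"E{e}",
                }
            )
    signature_regions = pd.DataFrame(sig_rows)

    # donor CNV: contiguous tile segments, donor 0 CNV-free
    seg_width = max(5, R // 20)
    C = np.ones((R, D))
    cnv_rows = []
    for d in range(1, D):
        placed: list[tuple[int, int]] = []
        for _ in range(config.cnv_segments_per_donor):
            for _try in range(500):
                c = int(rng.integers(0, config.n_chroms))
                lo, hi = chrom_offsets[c], chrom_offsets[c + 1]
                if hi - lo <= seg_width:
                    continue
                s = int(rng.integers(lo, hi - seg_width))
                e = s + seg_width
                if all(pe <= s or e <= pb for pb, pe in placed):
                    placed.append((s, e))
                    state = "gain" if rng.random() < 0.5 else "loss"
                    fold = config.cnv_fold if state == "gain" else 1.0 / config.cnv_fold
                    C[s:e, d] = fold
                    cnv_rows.append(
                        {
                            "donor": f"D{d}",
                            "chrom": regions["chrom"].iloc[s],
                            "start": int(regions["start"].iloc[s]),
                            "end": int(regions["end"].iloc[e - 1]),
                            "state": state,
                            "log2_fold": float(np.log2(fold)),
                            "first_tile": s,
                            "last_tile": e,
                        }
                    )
                    break
    cnv_profiles = pd.DataFrame(
        cnv_rows,
        columns=["donor", "chrom", "start", "end", "state", "log2_fold", "first_tile", "last_tile"],
    )

    depth = rng.lognormal(mean=np.log(config.depth_mean), sigma=0.3, size=N)
    cols = []
    data_parts, row_parts, col_parts = [], [], []
    for e in range(K):
        for d in range(D):
            cells_ed = np.flatnonzero((epigenotype == e) & (donor == d))
            if cells_ed.size == 0:
                continue
            w = W[:, e] * C[:, d]
            p = w / w.sum()
            lam = p[:, None] * depth[cells_ed][None, :]
            block = rng.poisson(lam)
            r_idx, c_idx = np.nonzero(block)
            data_parts.append(block[r_idx, c_idx])
            row_parts.append(r_idx)
            col_parts.append(cells_ed[c_idx])
    counts = sparse.csr_matrix(
        (
            np.concatenate(data_parts),
            (np.concatenate(row_parts), np.concatenate(col_parts)),
        ),
        shape=(R, N),
    )

    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(N)],
            "donor": [f"D{d}" for d in donor],
            "sample": [f"D{d}_s0" for d in donor],
            "tissue": np.where(donor == 0, "normal", "tumor"),
            "stage": np.where(donor == 0, "normal", np.where(donor % 2 == 1, "NMIBC", "MIBC")),
        }
    )
    labels = pd.Series(
        [f"E{e}" for e in epigenotype], index=cells["cell_id"], name="epigenotype"
    )
    cm = CellMatrix(regions=regions, cells=cells, counts=counts)
    return cm, labels, cnv_profiles, signature_regions


# ---------------------------------------------------------------------------
# joint clusters (stand-in for a trained co-embedding)


def simulate_joint_clusters(
    atac_labels: pd.Series,
    bridging_map: dict,
    n_rna_cells: int,
    seed: int = 0,
    noise_rate: float = 0.02,
) -> pd.DataFrame:
    """Joint-cluster table in which bridging epigenotypes span phenotypes.

    One joint cluster exists per (epigenotype, phenotype) mapped pair;
    ATAC cells of a bridging epigenotype are split uniformly across its
    phenotypes' joint clusters, RNA cells of a phenotype across the
    joint clusters that contain it.  ``noise_rate`` of cells are
    reassigned to a uniformly random joint cluster.

    This is a synthetic stand-in for a variational co-embedding's cluster
    output; no embedding model is trained.
    """
    rng = np.random.default_rng(seed)
    egs = sorted(set(atac_labels))
    for e in egs:
        if e not in bridging_map:
            raise ConfigError(f"bridging_map does not cover epigenotype {e}")
    for e, ps in bridging_map.items():
        if len(ps) == 0:
            raise ConfigError(f"empty phenotype set for {e}")
    phenos = sorted({p for ps in bridging_map.values() for p in ps})
    joint_of_pair = {
        (e, p): f"J_{e}_{p}" for e in bridging_map for p in sorted(bridging_map[e])
    }
    joint_ids = sorted(set(joint_of_pair.values()))

    rows = []
    for cell, e in atac_labels.items():
        p = sorted(bridging_map[e])[rng.integers(0, len(bridging_map[e]))]
        rows.append((cell, "ATAC", e, joint_of_pair[(e, p)]))
    clusters_with_pheno = {
        p: [j for (e2, p2), j in joint_of_pair.items() if p2 == p] for p in phenos
    }
    for i in range(n_rna_cells):
        p = phenos[i % len(phenos)]
        js = clusters_with_pheno[p]
        rows.append((f"rna{i:05d}", "RNA", p, js[rng.integers(0, len(js))]))

    table = pd.DataFrame(rows, columns=["cell_id", "modality", "source_cluster", "joint_cluster"])
    if noise_rate > 0:
        flip = rng.random(len(table)) < noise_rate
        table.loc[flip, "joint_cluster"] = [
            joint_ids[k] for k in rng.integers(0, len(joint_ids), size=int(flip.sum()))
        ]
    return table


# ---------------------------------------------------------------------------
# TCR


@dataclass(frozen=True)
class TcrSimConfig:
    """Power-law clonotype tables across multiple samples per donor."""

    n_donors: int = 6
    samples_per_donor: int = 3
    n_clones_per_donor: int = 150
    clone_size_power: float = 2.5
    multiplet_rate: float = 0.02
    max_clone_size: int = 40
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.multiplet_rate < 1.0):
            raise ConfigError("multiplet_rate must be in [0, 1)")
        if self.clone_size_power <= 1.0:
            raise ConfigError("clone_size_power must exceed 1")
        if min(self.n_donors, self.samples_per_donor, self.n_clones_per_donor) < 1:
            raise ConfigError("counts must be positive")


_NT = np.array(list("ACGT"))


def _random_cdr3(rng: np.random.Generator, length: int = 36) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def simulate_tcr(config: TcrSimConfig):
    """Return (per-cell chain table, per-clone truth table, donor table).

    Clone sizes follow a discrete power law (Zipf, truncated at
    ``max_clone_size``); each clone's cells are spread over the donor's
    samples by a Dirichlet-multinomial, which produces both local and
    global expansion patterns.  ``multiplet_rate`` of cells receive a
    third chain and are ground-truth multiplets; truth labels apply the
    expansion rules to the multiplet-free counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cell_rows, truth_rows, donor_rows = [], [], []
    barcode_n = 0
    for d in range(config.n_donors):
        donor = f"D{d}"
        stage = "NMIBC" if d % 2 == 0 else "MIBC"
        donor_rows.append({"donor": donor, "stage": stage})
        samples = [f"{donor}_s{j}" for j in range(config.samples_per_donor)]
        sizes = np.minimum(
            rng.zipf(config.clone_size_power, size=config.n_clones_per_donor),
            config.max_clone_size,
        )
        for ci, size in enumerate(sizes):
            clone = f"{donor}_c{ci:04d}"
            va, ja = rng.integers(1, 41), rng.integers(1, 62)
            vb, jb = rng.integers(1, 31), rng.integers(1, 3)
            chains = [
                ("TRA", f"TRAV{va}", f"TRAJ{ja}", "TRAC", _random_cdr3(rng)),
                ("TRB", f"TRBV{vb}", f"TRBJ{jb}-1", "TRBC1", _random_cdr3(rng)),
            ]
            probs = rng.dirichlet(np.full(config.samples_per_donor, 0.6))
            alloc = rng.multinomial(int(size), probs)
            clean_counts = dict.fromkeys(samples, 0)
            for sample, k in zip(samples, alloc):
                for _ in range(k):
                    barcode = f"bc{barcode_n:06d}"
                    barcode_n += 1
                    is_multiplet = rng.random() < config.multiplet_rate
                    cell_chains = list(chains)
                    if is_multiplet:
                        cell_chains.append(
                            ("TRB", f"TRBV{rng.integers(1, 31)}", "TRBJ1-1", "TRBC1", _random_cdr3(rng))
                        )
                    else:
                        clean_counts[sample] += 1
                    for locus, v, j, c, cdr3 in cell_chains:
                        cell_rows.append(
                            {
                                "barcode": barcode,
                                "donor": donor,
                                "sample": sample,
                                "chain": locus,
                                "v_gene": v,
                                "j_gene": j,
                                "c_gene": c,
                                "cdr3_nt": cdr3,
                            }
                        )
            counts = pd.Series(clean_counts)
            if counts.sum() > 0:
                label = classify_expansion_counts(counts)
                truth_rows.append(
                    {
                        "donor": donor,
                        "clone_id": clone,
                        "total": int(counts.sum()),
                        "label": label,
                        **{s: int(c) for s, c in counts.items()},
                    }
                )
    cells = pd.DataFrame(cell_rows)
    truth = pd.DataFrame(truth_rows)
    donors = pd.DataFrame(donor_rows)
    return cells, truth, donors


def classify_expansion_counts(counts: pd.Series) -> str:
    """Expansion label from a clone's per-sample count vector.

    Shared by the simulator's ground truth and (through the clone table)
    the pipeline path; the printed rules themselves are independently
    cross-checked against a brute-force enumerator in the test suite.
    """
    from .tcr import _label_from_counts

    return _label_from_counts(counts.to_numpy())


__all__ = [
    "ConfigError",
    "MethylSimConfig",
    "BetaMatrix",
    "simulate_methylation",
    "AtacSimConfig",
    "CellMatrix",
    "simulate_atac",
    "simulate_joint_clusters",
    "TcrSimConfig",
    "simulate_tcr",
]
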