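"""End-to-end demo pipeline over synthetic data.

``run_pipeline`` chains the stages — simulate, DMR calling, CNV calling
and masking, epigenotype clustering, transition graph, TCR clonality —
writes every artifact plus a provenance JSON (parameters, seed,
versions), and logs per-stage record counts.  Rerunning with the same
config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cnv, epigenotype, io, methylation, synth, tcr, transition

log = logging.getLogger("epibridge")

_DEFAULT_CONFIG = {
    "seed": 0,
    "methylation": {"n_loci": 6000, "n_chroms": 6, "n_dmrs": 6, "delta_beta": 0.3},
    "atac": {"n_cells": 400, "n_regions": 800, "n_epigenotypes": 3, "n_donors": 3},
    "joint": {"n_rna_cells": 400, "bridging_map": {"E0": ["P0", "P1", "P2"], "E1": ["P3"], "E2": ["P4"]}},
    "tcr": {"n_donors": 4, "n_clones_per_donor": 80},
    "dmr": {},
    "cnv": {},
    "epigenotype": {"k": 3, "d": 20},
    "transition": {"q": 0.15},
}


class PipelineConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    merged = {}
    for key, default in _DEFAULT_CONFIG.items():
        merged[key] = dict(default) if isinstance(default, dict) else default
    for key, val in config.items():
        if key not in _DEFAULT_CONFIG:
            raise PipelineConfigError(f"unknown config key: {key!r}")
        if isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


_current_stage = {"name": None}


def _stage(name):
    _current_stage["name"] = name
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: dict | None = None, outdir="epibridge_out") -> Path:
    config = validate_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    timings = {}

    try:
        t0 = _stage("simulate")
        mcfg = synth.MethylSimConfig(seed=seed, **config["methylation"])
        beta, truth_dmrs = synth.simulate_methylation(mcfg)
        acfg = synth.AtacSimConfig(seed=seed + 1, **config["atac"])
        cm, atac_labels_true, cnv_truth, _sig = synth.simulate_atac(acfg)
        joint = synth.simulate_joint_clusters(
            atac_labels_true.iloc[: len(atac_labels_true)],
            {k: set(v) for k, v in config["joint"]["bridging_map"].items()},
            n_rna_cells=config["joint"]["n_rna_cells"],
            seed=seed + 2,
        )
        tcfg = synth.TcrSimConfig(seed=seed + 3, **config["tcr"])
        tcr_cells, tcr_truth, tcr_donors = synth.simulate_tcr(tcfg)
        io.write_beta(beta, outdir / "beta.tsv", outdir / "groups.tsv")
        io.write_bed(truth_dmrs[["chrom", "start", "end"]], outdir / "true_dmrs.bed")
        io.write_mtx_bundle(cm, outdir / "atac")
        io.write_table(joint, outdir / "joint_clusters.tsv")
        io.write_table(tcr_cells, outdir / "tcr_cells.tsv")
        timings["simulate"] = time.time() - t0

        t0 = _stage("dmr")
        dmr_params = methylation.DmrParams(seed=seed, **config["dmr"])
        res = methylation.call_dmrs(beta, dmr_params)
        io.write_table(res.dml, outdir / "dml.tsv")
        dmr_bed = res.dmrs[["chrom", "start", "end", "n_loci", "mean_delta_beta", "provenance"]]
        io.write_bed(dmr_bed, outdir / "dmrs.bed")
        log.info("dmr: %d DML, %d seeds, %d final DMRs", len(res.dml),
                 int(res.seeds["is_seed"].sum()) if len(res.seeds) else 0, len(res.dmrs))
        timings["dmr"] = time.time() - t0

        t0 = _stage("cnv")
        donors = [d for d in sorted(cm.cells["donor"].unique()) if d != "D0"]
        masks = []
        for donor in donors:
            track = cnv.coverage_log_ratio(cm, cm.cells.set_index("cell_id")["donor"], donor, "D0")
            called = cnv.call_cnv_segments(track, seed=seed)
            called["donor"] = donor
            panel = cnv_truth[cnv_truth["donor"] == donor]
            masks.append(cnv.intersect_true_cnv(called, panel))
        cnv_mask = (
            pd.concat(masks, ignore_index=True)
            if masks
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        if len(cnv_mask):
            io.write_bed(cnv_mask, outdir / "cnv_mask.bed")
        kept_regions = cnv.mask_regions(cm.regions, cnv_mask)
        timings["cnv"] = time.time() - t0

        t0 = _stage("epigenotype")
        keep_idx = cm.regions.reset_index().merge(kept_regions, on=["chrom", "start", "end"])["index"].to_numpy()
        masked = synth.CellMatrix(
            regions=cm.regions.iloc[keep_idx].reset_index(drop=True),
            cells=cm.cells,
            counts=cm.counts[keep_idx, :],
        )
        emb = epigenotype.tfidf_lsi(masked, d=config["epigenotype"]["d"], seed=seed)
        labels = epigenotype.cluster_epigenotypes(emb, k=config["epigenotype"]["k"], seed=seed)
        div = epigenotype.donor_diversity(labels, cm.cells.set_index("cell_id")["donor"])
        io.write_table(labels.rename_axis("cell_id").reset_index(), outdir / "epigenotypes.tsv")
        io.write_table(div.rename_axis("epigenotype").reset_index(), outdir / "donor_diversity.tsv")
        timings["epigenotype"] = time.time() - t0

        t0 = _stage("transition")
        F = transition.frequency_matrix(joint)
        A = transition.adjacency(F)
        G = transition.denoise_top_quantile(A, q=config["transition"]["q"])
        report = transition.bridging_analysis(G)
        matches = transition.matches_from_joint(joint)
        atac_src = joint[joint["modality"] == "ATAC"].set_index("cell_id")["source_cluster"]
        plas = transition.plasticity_entropy(matches, atac_src)
        report["plasticity_entropy"] = plas.dropna().to_dict()
        io.write_json(report, outdir / "transition_report.json")
        edges = pd.DataFrame(
            [(str(u), str(v), d["weight"]) for u, v, d in G.edges(data=True)],
            columns=["node_a", "node_b", "weight"],
        )
        io.write_table(edges, outdir / "transition_edges.tsv")
        timings["transition"] = time.time() - t0

        t0 = _stage("tcr")
        kept, n_removed = tcr.filter_multiplets(tcr_cells)
        clones = tcr.define_clones(kept)
        labels_tcr = tcr.classify_expansion(clones)
        diversity = tcr.clonotype_diversity(clones, by="donor")
        prevalence = tcr.expansion_prevalence(labels_tcr, tcr_donors)
        io.write_table(clones, outdir / "clones.tsv")
        io.write_table(labels_tcr, outdir / "clone_labels.tsv")
        io.write_table(diversity.rename_axis("donor").reset_index(), outdir / "clonotype_diversity.tsv")
        log.info("tcr: %d multiplets removed, %d clones", n_removed, len(labels_tcr))
        timings["tcr"] = time.time() - t0
    except Exception as exc:  # tag failures with the failing stage
        raise RuntimeError(
            f"pipeline failed at stage '{_current_stage['name']}': {exc}"
        ) from exc

    provenance = {
        "package": "epibridge",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "local_expansion_prevalence": prevalence.to_dict(),
    }
    io.write_json(provenance, outdir / "provenance.json")
    return outdir
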