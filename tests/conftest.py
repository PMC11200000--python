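import numpy as np
import pandas as pd
import pytest

from epibridge import synth


@pytest.fixture(scope="session")
def small_beta():
    """6k-locus two-group beta matrix with 6 planted DMRs."""
    cfg = synth.MethylSimConfig(n_loci=6000, n_chroms=6, n_dmrs=6, seed=1)
    beta, truth = synth.simulate_methylation(cfg)
    return beta, truth


@pytest.fixture(scope="session")
def small_atac():
    """Small CNV-bearing accessibility simulation (3 donors, 3 epigenotypes)."""
    cfg = synth.AtacSimConfig(
        n_cells=450, n_regions=800, n_epigenotypes=3, n_donors=3,
        cnv_segments_per_donor=3, seed=7,
    )
    return synth.simulate_atac(cfg), cfg


@pytest.fixture(scope="session")
def bridging_table():
    """Joint-cluster table with one bridging epigenotype over 3 phenotypes."""
    atac_labels = pd.Series(
        [f"E{i % 4}" for i in range(240)],
        index=[f"atac{i:04d}" for i in range(240)],
    )
    bmap = {"E0": {"P0", "P1", "P2"}, "E1": {"P3"}, "E2": {"P4"}, "E3": {"P5"}}
    table = synth.simulate_joint_clusters(atac_labels, bmap, n_rna_cells=240, seed=3)
    return table, atac_labels, bmap


def brute_force_max_arc(x, min_seg=3):
    """Independent exhaustive arc search (double loop, textbook formulas)."""
    n = len(x)
    best = (-np.inf, 0, n)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_seg or n - k < min_seg:
                continue
            if 0 < i < min_seg or 0 < n - j < min_seg:
                continue
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            m_in, m_out = arc.mean(), rest.mean()
            ss = ((arc - m_in) ** 2).sum() + ((rest - m_out) ** 2).sum()
            s2 = ss / max(n - 2, 1)
            d = abs(m_in - m_out)
            if s2 < 1e-20:
                t = np.inf if d > 1e-10 else 0.0
            else:
                t = d / np.sqrt(s2 * (1 / k + 1 / (n - k)))
            if t > best[0]:
                best = (t, i, j)
    return best
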