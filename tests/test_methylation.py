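"""DMR pipeline stages against independent oracles and constructed cases."""

import numpy as np
import pandas as pd
import pytest

from epibridge import methylation as M
from epibridge.synth import BetaMatrix, MethylSimConfig, simulate_methylation


def make_beta(values, positions=None, chroms=None):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    assert s % 2 == 0
    positions = np.arange(n) * 10 if positions is None else np.asarray(positions)
    chroms = ["chr1"] * n if chroms is None else chroms
    return BetaMatrix(
        loci=pd.DataFrame({"chrom": chroms, "pos": positions}),
        values=values,
        samples=[f"s{i}" for i in range(s)],
        group=np.array(["case"] * (s // 2) + ["control"] * (s // 2)),
    )


def welch_ttest(a, b):
    """Textbook Welch t-test, independent of scipy."""
    from math import sqrt

    from scipy.stats import t as tdist  # distribution function only

    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)


class TestCallDml:
    def test_strong_locus_matches_independent_welch(self):
        rng = np.random.default_rng(0)
        vals = np.array([[0.9, 0.9, 0.9, 0.1, 0.1, 0.1]]) + rng.normal(0, 1e-3, (1, 6))
        beta = make_beta(np.clip(vals, 0, 1))
        dml = M.call_dml(beta)
        assert len(dml) == 1
        rec = dml.iloc[0]
        assert rec["delta_beta"] == pytest.approx(0.8, abs=0.01)
        assert rec["direction"] == "hyper"
        t, p = welch_ttest(vals[0, :3], vals[0, 3:])
        assert rec["p_value"] == pytest.approx(p, rel=1e-9)

    def test_identical_groups_not_dml(self):
        beta = make_beta([[0.5, 0.6, 0.7, 0.5, 0.6, 0.7]])
        assert len(M.call_dml(beta)) == 0

    def test_small_delta_fails_delta_criterion_despite_tiny_p(self):
        rng = np.random.default_rng(1)
        case = 0.50 + rng.normal(0, 0.001, (1, 20))
        ctrl = 0.45 + rng.normal(0, 0.001, (1, 20))
        beta = make_beta(np.hstack([case, ctrl]))
        dml = M.call_dml(beta)
        _, p = welch_ttest(case[0], ctrl[0])
        assert p < 1e-8  # hugely significant ...
        assert len(dml) == 0  # ... but |delta beta| = 0.05 <= 0.1

    def test_invariance_to_column_order_and_label_swap(self):
        rng = np.random.default_rng(2)
        vals = np.clip(rng.beta(2, 2, (50, 8)), 0, 1)
        vals[10:15, :4] += 0.4
        vals = np.clip(vals, 0, 1)
        beta = make_beta(vals)
        dml = M.call_dml(beta)
        perm = rng.permutation(8)
        beta_perm = BetaMatrix(
            loci=beta.loci, values=vals[:, perm],
            samples=[beta.samples[i] for i in perm], group=beta.group[perm],
        )
        dml_perm = M.call_dml(beta_perm)
        pd.testing.assert_frame_equal(dml, dml_perm)
        swapped = np.where(beta.group == "case", "control", "case")
        beta_swap = BetaMatrix(loci=beta.loci, values=vals, samples=beta.samples, group=swapped)
        dml_swap = M.call_dml(beta_swap)
        assert np.allclose(dml_swap["delta_beta"].to_numpy(), -dml["delta_beta"].to_numpy())


class TestMergeDml:
    def test_gap_arithmetic_splits_at_gap_over_100(self):
        dml = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [100, 150, 260],
                "p_value": [1e-5] * 3,
                "delta_beta": [0.5] * 3,
                "direction": ["hyper"] * 3,
                "locus_idx": [0, 1, 2],
            }
        )
        cands = M.merge_dml(dml, max_gap_bp=100)
        assert len(cands) == 2
        assert cands.iloc[0][["start", "end", "n_loci"]].tolist() == [100, 151, 2]
        assert cands.iloc[1][["start", "end", "n_loci"]].tolist() == [260, 261, 1]

    def test_single_dml_and_chromosome_boundary(self):
        dml = pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "pos": [100, 120],
                "p_value": [1e-5] * 2,
                "delta_beta": [0.5] * 2,
                "direction": ["hyper"] * 2,
                "locus_idx": [0, 1],
            }
        )
        cands = M.merge_dml(dml)
        assert len(cands) == 2  # never merged across chromosomes

    def test_empty_input(self):
        assert len(M.merge_dml(pd.DataFrame(columns=["chrom", "pos", "locus_idx"]))) == 0


class TestSeedDmrs:
    def test_separating_candidate_is_seed_with_independent_pvalue(self):
        rng = np.random.default_rng(3)
        vals = np.clip(0.1 + rng.normal(0, 0.01, (10, 8)), 0, 1)
        vals[2:6, :4] += 0.8
        vals = np.clip(vals, 0, 1)
        beta = make_beta(vals)
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [20], "end": [60], "n_loci": [4]})
        out = M.test_seed_dmrs(beta, cand)
        assert bool(out["is_seed"].iloc[0])
        per_sample = vals[2:6].mean(axis=0)
        _, p = welch_ttest(per_sample[:4], per_sample[4:])
        assert out["p_value"].iloc[0] == pytest.approx(p, rel=1e-9)

    def test_cancelling_effects_not_seed(self):
        vals = np.full((4, 6), 0.5)
        vals[0, :3] += 0.3  # hyper locus
        vals[1, :3] -= 0.3  # hypo locus cancels the per-sample mean
        beta = make_beta(vals)
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20], "n_loci": [2]})
        out = M.test_seed_dmrs(beta, cand)
        assert not bool(out["is_seed"].iloc[0])

    def test_zero_locus_candidate_raises(self):
        beta = make_beta(np.full((4, 6), 0.5))
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [950], "n_loci": [1]})
        with pytest.raises(ValueError):
            M.test_seed_dmrs(beta, cand)


def dp_kmeans_1d(values, k):
    """Optimal 1-D k-means by dynamic programming (independent oracle)."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    pre = np.concatenate(([0.0], np.cumsum(x)))
    pre2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(i, j):  # sse of x[i:j]
        s, q, m = pre[j] - pre[i], pre2[j] - pre2[i], j - i
        return q - s * s / m

    D = np.full((k + 1, n + 1), np.inf)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                c = D[kk - 1, i] + cost(i, j)
                if c < D[kk, j]:
                    D[kk, j] = c
                    arg[kk, j] = i
    # recover partition boundaries
    bounds = [n]
    j = n
    for kk in range(k, 0, -1):
        j = arg[kk, j]
        bounds.append(j)
    bounds = sorted(bounds)
    labels = np.zeros(n, dtype=int)
    for ci, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        labels[a:b] = ci
    order = np.argsort(values, kind="stable")
    out = np.empty(n, dtype=int)
    out[order] = labels
    return out


class TestClusterSegments:
    def _segments(self, means):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(means),
                "start": np.arange(len(means)) * 100,
                "end": np.arange(len(means)) * 100 + 50,
                "n_loci": 5,
                "mean_delta_beta": means,
            }
        )

    def test_three_well_separated_groups_match_dp_oracle(self):
        means = [-0.3, -0.29, 0.0, 0.01, 0.3, 0.31]
        seg = M.cluster_segments(self._segments(means), k=3, seed=0)
        oracle = dp_kmeans_1d(means, 3)
        # same partition, and labels ordered by centroid
        assert seg["kmeans_cluster"].tolist() == oracle.tolist() == [0, 0, 1, 1, 2, 2]

    def test_k_one_and_k_too_large(self):
        seg = M.cluster_segments(self._segments([0.1, 0.2, 0.3]), k=1, seed=0)
        assert (seg["kmeans_cluster"] == 0).all()
        with pytest.raises(ValueError):
            M.cluster_segments(self._segments([0.1]), k=2, seed=0)

    def test_duplicate_means_deterministic(self):
        means = [0.1, 0.1, 0.1, 0.5, 0.5, 0.5]
        a = M.cluster_segments(self._segments(means), k=2, seed=0)
        b = M.cluster_segments(self._segments(means), k=2, seed=0)
        pd.testing.assert_frame_equal(a, b)
        assert a["kmeans_cluster"].tolist() == [0, 0, 0, 1, 1, 1]


class TestSelectTrueDmrs:
    def _segments(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [800, 2000, 0],
                "end": [2000, 3000, 1000],
                "n_loci": [10, 10, 10],
                "mean_delta_beta": [0.3, 0.0, 0.0],
                "kmeans_cluster": [2, 1, 1],
            }
        )

    def _seed(self, chrom, start, end):
        return pd.DataFrame(
            {"chrom": [chrom], "start": [start], "end": [end], "is_seed": [True]}
        )

    def test_contained_seed_selects_whole_cluster(self):
        out = M.select_true_dmrs(self._segments(), self._seed("chr1", 1000, 1200))
        assert out["start"].tolist() == [800]
        assert (out["provenance"] == "segment-cluster").all()

    def test_straddling_seed_selects_nothing(self):
        out = M.select_true_dmrs(self._segments(), self._seed("chr1", 1900, 2100))
        assert len(out) == 0

    def test_all_seeds_in_one_cluster_returns_that_cluster_only(self):
        segs = self._segments()
        seeds = pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "start": [900, 100],
                "end": [1000, 200],
                "is_seed": [True, True],
            }
        )
        out = M.select_true_dmrs(segs, seeds)
        # seed 1 in cluster 2 segment, seed 2 in cluster 1 segment
        assert sorted(out["kmeans_cluster"].unique()) == [1, 2]
        only_first = M.select_true_dmrs(segs, seeds.iloc[:1])
        assert sorted(only_first["kmeans_cluster"].unique()) == [2]

    def test_no_seeds_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = M.select_true_dmrs(self._segments(), self._seed("chr1", 0, 1)[0:0])
        assert len(out) == 0


class TestEndToEnd:
    def test_planted_recovery_and_stored_means_match_matrix(self, small_beta):
        beta, truth = small_beta
        res = M.call_dmrs(beta)
        from epibridge.regions import overlaps_any

        sens = overlaps_any(truth[["chrom", "start", "end"]], res.dmrs).mean()
        prec = overlaps_any(res.dmrs, truth[["chrom", "start", "end"]]).mean()
        assert sens >= 0.9 and prec >= 0.9
        # stored segment means agree with direct recomputation to 1e-9
        case = beta.values[:, beta.case_mask]
        ctrl = beta.values[:, ~beta.case_mask]
        delta = case.mean(axis=1) - ctrl.mean(axis=1)
        chrom_arr = beta.loci["chrom"].to_numpy()
        pos_arr = beta.loci["pos"].to_numpy()
        for rec in res.dmrs.itertuples(index=False):
            sel = (chrom_arr == rec.chrom) & (pos_arr >= rec.start) & (pos_arr < rec.end)
            assert abs(delta[sel].mean() - rec.mean_delta_beta) < 1e-9
        # output disjoint and sorted within chromosome
        for _, sub in res.dmrs.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_label_permutation_collapses_recovery(self, small_beta):
        beta, truth = small_beta
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(beta.samples))
        # permuting group labels over columns destroys the group structure
        shuffled = BetaMatrix(
            loci=beta.loci, values=beta.values, samples=beta.samples,
            group=beta.group[perm],
        )
        res = M.call_dmrs(shuffled)
        assert len(res.dmrs) <= 1
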