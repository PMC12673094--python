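"""Beta-matrix operations: merge, correlation, PCA, context tests, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.stats import mannwhitneyu, rankdata

from conftest import make_matrix
from epimask.beta import (
    BetaMatrix,
    cluster_samples,
    global_context_methylation,
    merge_platform_matrices,
    pc_covariate_association,
    pca_top_variable,
    replicate_correlation,
)
from epimask.simulate import SimulationSpec, simulate_beta_cohort, simulate_replicate_pairs


def coords_for(n, spacing=1000):
    return {"chrom": ["chr1"] * n, "cpg_pos": [1000 + i * spacing for i in range(n)]}


class TestMerge:
    def _pair(self):
        rng = np.random.default_rng(0)
        a = make_matrix(rng.random((5, 3)), coords=coords_for(5))
        bvals = rng.random((4, 2))
        b = BetaMatrix(
            values=pd.DataFrame(bvals, index=[f"x{i}" for i in range(4)],
                                columns=["t0", "t1"]),
            coords=pd.DataFrame(
                {"chrom": ["chr1"] * 4,
                 "cpg_pos": [1000, 2000, 3000, 999_999]},  # 3 shared, 1 unique
                index=[f"x{i}" for i in range(4)]),
        )
        return a, b

    def test_intersection_by_coordinate(self):
        a, b = self._pair()
        merged = merge_platform_matrices(a, b)
        assert merged.n_probes == 3
        assert merged.n_samples == 5
        assert set(merged.covariates["platform"]) == {"a", "b"}

    def test_probe_content_commutative(self):
        a, b = self._pair()
        m1 = merge_platform_matrices(a, b)
        m2 = merge_platform_matrices(b, a)
        key1 = set(map(tuple, m1.coords[["chrom", "cpg_pos"]].to_numpy()))
        key2 = set(map(tuple, m2.coords[["chrom", "cpg_pos"]].to_numpy()))
        assert key1 == key2

    def test_self_merge_with_renamed_samples_keeps_rows(self):
        a, _ = self._pair()
        b = BetaMatrix(values=a.values.rename(columns=lambda c: f"{c}_r"),
                       coords=a.coords)
        merged = merge_platform_matrices(a, b)
        assert merged.n_probes == a.n_probes

    def test_disjoint_probe_sets_error(self):
        a, _ = self._pair()
        b = BetaMatrix(values=a.values.rename(columns=lambda c: f"{c}_r"),
                       coords=a.coords.assign(chrom="chr9"))
        with pytest.raises(ValueError, match="no probes shared"):
            merge_platform_matrices(a, b)

    def test_duplicate_sample_ids_error(self):
        a, _ = self._pair()
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_platform_matrices(a, BetaMatrix(values=a.values, coords=a.coords))


class TestReplicateCorrelation:
    def test_identical_and_antiranked_vectors(self):
        x = np.linspace(0.1, 0.9, 20)
        m = make_matrix(np.column_stack([x, x, x[::-1]]))
        out = replicate_correlation(m, [("s000", "s001"), ("s000", "s002")])
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[1, "rho"] == pytest.approx(-1.0)

    def test_constant_vector_flagged_undefined(self):
        m = make_matrix(np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10)]))
        out = replicate_correlation(m, [("s000", "s001")])
        assert bool(out.loc[0, "undefined"])

    def test_simulated_replicates_correlate_highly(self):
        spec = SimulationSpec(seed=3, n_probes=10_000)
        m, _ = simulate_beta_cohort(spec)
        withreps, pairs = simulate_replicate_pairs(m, sigma=0.01, n_pairs=4, seed=5)
        out = replicate_correlation(withreps, pairs)
        assert (out["rho"] > 0.99).all()


class TestPCA:
    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(1)
        x = rng.random(50)
        m = make_matrix(np.column_stack([x, x, rng.random(50)]))
        res = pca_top_variable(m, k=50)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[1], atol=1e-9)

    def test_planted_clusters_dominate_pc1_and_match_eigh_oracle(self):
        rng = np.random.default_rng(2)
        n = 500
        base = rng.random(n) * 0.4 + 0.2
        X = np.empty((n, 20))
        for j in range(20):
            shift = 0.3 if j >= 10 else 0.0
            X[:, j] = np.clip(base + shift + rng.normal(0, 0.02, n), 0, 1)
        m = make_matrix(X)
        res = pca_top_variable(m, k=500)
        assert res.variance_fraction[0] > 0.5
        g1 = res.scores.iloc[:10, 0].to_numpy()
        g2 = res.scores.iloc[10:, 0].to_numpy()
        assert g1.max() < g2.min() or g2.max() < g1.min()  # PC1 separates clusters
        # dense eigen-decomposition oracle on the sample covariance
        Xc = X.T - X.T.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh((Xc.T @ Xc) / (20 - 1)))[::-1]
        np.testing.assert_allclose(
            res.variance_fraction[0], evals[0] / evals.sum(), atol=1e-8)

    def test_variance_fractions_recompute_from_scores(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.random((100, 8)))
        res = pca_top_variable(m, k=60)
        sc = res.scores.to_numpy()
        frac = sc.var(axis=0, ddof=1) / sc.var(axis=0, ddof=1).sum()
        np.testing.assert_allclose(res.variance_fraction[: len(frac)], frac, atol=1e-8)

    def test_k_capped_with_fewer_probes(self):
        m = make_matrix(np.random.default_rng(0).random((10, 4)))
        res = pca_top_variable(m, k=10_000)
        assert res.n_positions == 10

    def test_single_sample_rejected(self):
        m = make_matrix(np.random.default_rng(0).random((10, 1)))
        with pytest.raises(ValueError):
            pca_top_variable(m)


class TestPCCovariateAssociation:
    def test_perfectly_separating_binary_covariate(self):
        rng = np.random.default_rng(3)
        n = 300
        X = np.clip(0.5 + np.concatenate(
            [np.full((n, 10), -0.15), np.full((n, 10), 0.15)], axis=1)
            + rng.normal(0, 0.02, (n, 20)), 0, 1)
        m = make_matrix(X, group=["A"] * 10 + ["B"] * 10)
        res = pca_top_variable(m, k=n)
        table = pc_covariate_association(res, m.covariates)
        p1 = table[(table.component == "PC1") & (table.covariate == "group")]
        assert p1["p_value"].iloc[0] < 1e-6

    def test_continuous_covariate_equal_to_scores(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.random((100, 12)))
        res = pca_top_variable(m, k=100)
        cov = pd.DataFrame({"pc1_copy": res.scores["PC1"]}, index=res.scores.index)
        table = pc_covariate_association(res, cov)
        row = table[(table.component == "PC1") & (table.covariate == "pc1_copy")]
        assert abs(row["statistic"].iloc[0]) == pytest.approx(1.0)

    def test_single_level_covariate_skipped(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.random((50, 6)), group=["A"] * 6)
        res = pca_top_variable(m, k=50)
        table = pc_covariate_association(res, m.covariates)
        assert table.empty or "group" not in set(table["covariate"])


class TestGlobalContextMethylation:
    def test_planted_shift_detected_by_rank_test(self):
        rng = np.random.default_rng(8)
        n_line1 = 60
        base = np.clip(rng.normal(0.6, 0.05, (n_line1, 40)), 0, 1)
        base[:, 20:] = np.clip(base[:, 20:] + 0.2, 0, 1)
        m = make_matrix(base, group=["A"] * 20 + ["B"] * 20)
        contexts = {"LINE-1": list(m.values.index)}
        medians, tests = global_context_methylation(m, contexts, "group")
        assert tests.loc[0, "p_value"] < 0.001
        assert medians.shape == (40, 1)

    def test_identical_groups_not_significant(self):
        x = np.tile(np.linspace(0.2, 0.8, 30)[:, None], (1, 10))
        m = make_matrix(x, group=["A"] * 5 + ["B"] * 5)
        _, tests = global_context_methylation(m, {"CGI": list(m.values.index)}, "group")
        assert tests.loc[0, "p_value"] == pytest.approx(1.0, abs=0.05)

    def test_single_probe_context_median_is_that_probe(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.random((5, 8)), group=["A"] * 4 + ["B"] * 4)
        pid = m.values.index[2]
        medians, _ = global_context_methylation(m, {"solo": [pid]}, "group")
        np.testing.assert_allclose(medians["solo"], m.values.loc[pid])

    def test_small_groups_match_exact_enumeration(self):
        """Rank-sum p at n<=8 equals brute-force enumeration over assignments."""
        rng = np.random.default_rng(12)
        x = rng.random(5)
        y = rng.random(4)
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        n1 = len(x)
        u_obs = res.statistic
        count = 0
        total = 0
        for comb in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            u_alt = len(x) * len(y) - u
            if min(u, u_alt) <= min(u_obs, len(x) * len(y) - u_obs):
                count += 1
            total += 1
        assert res.pvalue == pytest.approx(count / total, abs=1e-9)


class TestClustering:
    def test_identical_samples_merge_first_at_zero_height(self):
        rng = np.random.default_rng(2)
        x = rng.random(20)
        m = make_matrix(np.column_stack([x, x, rng.random(20)]))
        out = cluster_samples(m, list(m.values.index))
        Z = out["linkage"]
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_outlier_joins_last_hand_computed(self):
        # samples: a=(0,0), b=(0.1,0), c=(0.9,0.9); Euclidean distances by hand:
        # d(a,b)=0.1, d(a,c)=sqrt(1.62)~1.27, d(b,c)=sqrt(0.64+0.81)~1.20
        vals = np.array([[0.0, 0.1, 0.9], [0.0, 0.0, 0.9]])
        m = make_matrix(vals)
        out = cluster_samples(m, list(m.values.index))
        Z = out["linkage"]
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.1)
        labels = fcluster(Z, 2, criterion="maxclust")
        assert labels[2] != labels[0] and labels[0] == labels[1]

    def test_duplicated_probe_rows_scale_heights_by_sqrt2(self):
        rng = np.random.default_rng(7)
        vals = rng.random((15, 5))
        m1 = make_matrix(vals)
        m2 = make_matrix(np.vstack([vals, vals]))
        Z1 = cluster_samples(m1, list(m1.values.index))["linkage"]
        Z2 = cluster_samples(m2, list(m2.values.index))["linkage"]
        np.testing.assert_allclose(Z2[:, 2], Z1[:, 2] * np.sqrt(2), atol=1e-9)
        np.testing.assert_array_equal(Z1[:, :2], Z2[:, :2])

    def test_missing_values_rejected(self):
        vals = np.random.default_rng(0).random((5, 3))
        vals[0, 0] = np.nan
        m = make_matrix(vals)
        with pytest.raises(ValueError, match="missing"):
            cluster_samples(m, list(m.values.index))
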