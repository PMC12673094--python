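"""DMP fitting, BH correction, DMR calling and variance heterogeneity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from epimask.differential import (
    DMRConfig,
    benjamini_hochberg,
    call_dmrs,
    fit_dmps,
    smooth_squared_stats,
    variance_heterogeneity_test,
)
from epimask.simulate import SimulationSpec, simulate_beta_cohort


def bh_oracle(pvals):
    """Textbook step-up: q_i = min over j>=i of m*p_(j)/j, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for m in range(1, 13):
            for _ in range(20):
                p = rng.random(m)
                np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    def test_monotone_along_sorted_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFitDmps:
    def test_null_cohort_yields_no_significant_probes(self, null_cohort):
        res = fit_dmps(null_cohort, group="group")
        assert res["significant"].sum() == 0
        assert res["q"].min() > 0.05 or res["delta_beta"].abs().max() < 0.20

    def test_planted_effect_detected(self, small_cohort):
        m, truth = small_cohort
        res = fit_dmps(m, group="group", delta_beta_min=0.20)
        for pid, delta in truth["dmp_probes"].items():
            assert bool(res.loc[pid, "significant"]), pid
            assert np.sign(res.loc[pid, "delta_beta"]) == np.sign(delta)

    def test_delta_beta_is_raw_group_mean_difference(self, small_cohort):
        m, _ = small_cohort
        res = fit_dmps(m, group="group")
        g = m.covariates["group"]
        pid = res.index[0]
        expected = (m.values.loc[pid, g[g == "B"].index].mean()
                    - m.values.loc[pid, g[g == "A"].index].mean())
        assert res.loc[pid, "delta_beta"] == pytest.approx(expected)

    def test_covariate_adjustment_changes_adjusted_delta_only(self, small_cohort):
        m, _ = small_cohort
        plain = fit_dmps(m, group="group")
        adjusted = fit_dmps(m, group="group", adjust=["age"])
        pd.testing.assert_series_equal(plain["delta_beta"], adjusted["delta_beta"])

    def test_zero_variance_probe_excluded(self):
        rng = np.random.default_rng(3)
        vals = rng.random((10, 8)).clip(0.01, 0.99)
        vals[0, :] = 0.5  # constant probe
        m = make_matrix(vals, group=["A"] * 4 + ["B"] * 4)
        res = fit_dmps(m, group="group")
        assert "cg000000" not in res.index
        assert res.attrs["n_excluded_zero_variance"] == 1

    def test_tiny_group_rejected(self):
        m = make_matrix(np.random.default_rng(0).random((5, 3)),
                        group=["A", "A", "B"])
        with pytest.raises(ValueError):
            fit_dmps(m, group="group")


class TestSmoothing:
    def test_large_scale_factor_degenerates_to_per_cpg_statistic(self):
        """As C -> infinity the kernel collapses to the probe itself."""
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(100_000, 50, replace=False)).astype(float)
        t2 = rng.chisquare(1, 50)
        S, p = smooth_squared_stats(pos, t2, lambda_bp=1000.0, scale_c=1e9)
        np.testing.assert_allclose(S, t2, rtol=1e-6)
        from scipy.stats import chi2
        np.testing.assert_allclose(p, chi2.sf(t2, 1), rtol=1e-5)

    def test_satterthwaite_moments_match_definition(self):
        pos = np.array([0.0, 100.0, 200.0])
        t2 = np.array([1.0, 4.0, 9.0])
        lam, C = 1000.0, 2.0
        sigma = lam / C
        w = np.exp(-((pos - pos[1]) ** 2) / (2 * sigma**2))
        S, _ = smooth_squared_stats(pos, t2, lam, C)
        assert S[1] == pytest.approx(float(w @ t2))


class TestCallDmrs:
    def _dmps_from(self, m, truth):
        return fit_dmps(m, group="group")

    def test_planted_region_recovered(self):
        spec = SimulationSpec(seed=31, n_probes=400, n_dmrs=3)
        m, truth = simulate_beta_cohort(spec)
        res = fit_dmps(m, group="group")
        regions = call_dmrs(res, DMRConfig(delta_beta_min=0.10))
        assert len(regions) >= 3
        for tr in truth["dmr_regions"]:
            hit = [r for r in regions
                   if r.chrom == tr["chrom"]
                   and r.start <= tr["end"] and r.end >= tr["start"]]
            assert hit, tr["region_id"]
            # boundary error within the smoothing bandwidth
            r = hit[0]
            assert abs(r.start - tr["start"]) <= 1000
            assert abs(r.end - tr["end"]) <= 1000

    def test_fewer_than_min_cpgs_never_forms_region(self):
        # 4 strongly significant CpGs in one tight cluster, null elsewhere
        rng = np.random.default_rng(6)
        n = 200
        pos = 1000 + np.arange(n) * 3000
        pos[100:104] = 500_000 + np.arange(4) * 100
        frame = pd.DataFrame({
            "chrom": "chr1", "cpg_pos": np.sort(pos),
            "t": rng.normal(0, 1, n), "delta_beta": rng.normal(0, 0.01, n),
        }, index=[f"cg{i}" for i in range(n)])
        tight = (frame["cpg_pos"] >= 500_000) & (frame["cpg_pos"] <= 500_400)
        frame.loc[tight, "t"] = 12.0
        frame.loc[tight, "delta_beta"] = 0.35
        frame["p"] = 2 * (1 - 0.999999)  # placeholder, recomputed below
        from scipy.stats import t as tdist
        frame["p"] = 2 * tdist.sf(frame["t"].abs(), df=38)
        regions = call_dmrs(frame, DMRConfig(min_cpgs=5, delta_beta_min=0.1))
        assert all(r.n_cpgs >= 5 for r in regions)
        assert not any(r.start >= 490_000 and r.end <= 510_000 and r.n_cpgs < 5
                       for r in regions)

    def test_distant_clusters_never_merge(self):
        from scipy.stats import t as tdist
        rows = []
        for block, offset in enumerate([100_000, 105_000]):  # 5 kb apart
            for j in range(6):
                rows.append({"chrom": "chr1", "cpg_pos": offset + j * 100,
                             "t": 10.0, "delta_beta": 0.3})
        frame = pd.DataFrame(rows, index=[f"cg{i}" for i in range(len(rows))])
        frame["p"] = 2 * tdist.sf(frame["t"].abs(), df=38)
        regions = call_dmrs(frame, DMRConfig(min_cpgs=5, delta_beta_min=0.1))
        assert len(regions) == 2
        assert all(r.end - r.start < 2000 for r in regions)

    def test_null_input_rarely_yields_regions(self):
        spec = SimulationSpec(seed=41, n_probes=600)
        m, _ = simulate_beta_cohort(spec)
        res = fit_dmps(m, group="group")
        regions = call_dmrs(res, DMRConfig(delta_beta_min=0.10))
        assert len(regions) == 0

    def test_unsorted_input_sorted_internally(self):
        spec = SimulationSpec(seed=31, n_probes=200, n_dmrs=2)
        m, _ = simulate_beta_cohort(spec)
        res = fit_dmps(m, group="group")
        shuffled = res.sample(frac=1.0, random_state=0)
        r1 = call_dmrs(res, DMRConfig(delta_beta_min=0.10))
        r2 = call_dmrs(shuffled, DMRConfig(delta_beta_min=0.10))
        assert [(r.chrom, r.start, r.end) for r in r1] == \
               [(r.chrom, r.start, r.end) for r in r2]


class TestVarianceHeterogeneity:
    def test_unequal_spread_detected_and_attributed(self):
        rng = np.random.default_rng(8)
        x = np.clip(np.concatenate([
            rng.normal(0.5, 0.02, (30, 20)), rng.normal(0.5, 0.15, (30, 20))
        ], axis=1), 0, 1)
        m = make_matrix(x, group=["A"] * 20 + ["B"] * 20)
        res = variance_heterogeneity_test(m, list(m.values.index)[:30], "group")
        assert (res["p"] < 0.01).mean() > 0.8
        assert (res["more_variable"] == "B").all()

    def test_type_i_error_calibrated_under_equal_variance(self):
        rng = np.random.default_rng(9)
        x = np.clip(rng.normal(0.5, 0.05, (200, 100)), 0, 1)
        m = make_matrix(x, group=["A"] * 50 + ["B"] * 50)
        res = variance_heterogeneity_test(m, list(m.values.index), "group")
        assert (res["p"] < 0.05).mean() < 0.10  # near-nominal false positive rate
        # p-values roughly uniform: mean near 0.5
        assert abs(res["p"].mean() - 0.5) < 0.1

    def test_constant_probe_flagged_undefined(self):
        x = np.full((3, 8), 0.5)
        x[1] = np.linspace(0.1, 0.8, 8)
        m = make_matrix(x, group=["A"] * 4 + ["B"] * 4)
        res = variance_heterogeneity_test(m, list(m.values.index), "group")
        assert bool(res.iloc[0]["undefined"])
        assert not bool(res.iloc[1]["undefined"])

    def test_group_of_two_rejected(self):
        m = make_matrix(np.random.default_rng(0).random((4, 5)),
                        group=["A", "A", "B", "B", "B"])
        with pytest.raises(ValueError):
            variance_heterogeneity_test(m, list(m.values.index), "group")
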