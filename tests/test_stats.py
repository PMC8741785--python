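"""OLS, weather PCA, K-means + K selection, penalized-spline smooths."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isobase.stats import (compare_signal, fit_linear_term, fit_smooth,
                           kmeans_cluster, ols, pca_weather, select_k)


class TestOls:
    def test_perfect_fit(self):
        x = np.arange(10, dtype=float)
        res = ols(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_residual_null_case(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even in x: zero covariance
        res = ols(x, y)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(0, 2, 5)
        y = rng.normal(0, 1, 5)
        res = ols(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ols(np.ones(5), np.arange(5.0))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_r_squared_invariant_to_constant_shifts(self, kx, ky):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = 0.7 * x + rng.normal(0, 0.5, 30)
        base = ols(x, y).r_squared
        assert ols(x + kx, y + ky).r_squared == pytest.approx(base, abs=1e-7)


def weather_matrix(rng, n=40):
    t = rng.normal(8, 3, n)
    return pd.DataFrame({
        "w14_t_mean": t,
        "w14_t_max": t + 3 + rng.normal(0, 0.01, n),
        "w14_t_min": t - 3 + rng.normal(0, 0.01, n),
        "w14_rain_mm": rng.gamma(2, 2, n),
        "w14_sun_hrs": rng.uniform(1, 8, n),
    })


class TestPcaWeather:
    def test_block_structure_separates_temperature_from_rain(self, rng):
        X = weather_matrix(rng, 200)
        comps = pca_weather(X)
        load = dict(zip(comps.columns, comps.loadings[:, 0]))
        assert abs(load["w14_rain_mm"]) < 0.05
        assert load["w14_t_mean"] > 0.5
        rain_pc2 = dict(zip(comps.columns, comps.loadings[:, 1]))["w14_rain_mm"]
        assert rain_pc2 > 0.5

    def test_variance_explained_sums_to_correlation_total(self, rng):
        comps = pca_weather(weather_matrix(rng))
        assert comps.variance_explained.sum() == pytest.approx(5.0, abs=1e-9)
        assert np.all(np.diff(comps.variance_explained) <= 1e-12)

    def test_loadings_orthonormal_and_match_eigh_oracle(self, rng):
        X = weather_matrix(rng, 8)
        comps = pca_weather(X)
        np.testing.assert_allclose(comps.loadings.T @ comps.loadings,
                                   np.eye(5), atol=1e-10)
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        vals, vecs = np.linalg.eigh(corr)
        for j in range(5):  # match up to sign
            v = comps.loadings[:, j]
            o = vecs[:, np.argsort(vals)[::-1][j]]
            assert min(np.abs(v - o).max(), np.abs(v + o).max()) < 1e-8
        np.testing.assert_allclose(np.sort(comps.variance_explained),
                                   np.sort(vals), atol=1e-10)

    def test_constant_column_named(self, rng):
        X = weather_matrix(rng)
        X["w14_rain_mm"] = 1.0
        with pytest.raises(ValueError, match="w14_rain_mm"):
            pca_weather(X)


def brute_force_kmeans(Z, k):
    """Exhaustive-partition minimum total within-cluster SS."""
    n = len(Z)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        wss = 0.0
        for c in range(k):
            pts = Z[np.array(assign) == c]
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


class TestKmeans:
    def test_k_equals_n_zero_wss(self, rng):
        X = rng.normal(0, 1, (6, 3))
        res = kmeans_cluster(X, k=6, seed=0)
        assert res.total_within_ss == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.assignments) == list(range(1, 7))

    def test_two_distant_blobs_recovered_perfectly(self, rng):
        labels = np.repeat(["u", "v"], 20)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(20, 1, (20, 3))])
        res = kmeans_cluster(X, k=2, seed=0, land_class=labels)
        a = res.assignments
        assert len(np.unique(a[:20])) == 1 and len(np.unique(a[20:])) == 1
        assert a[0] != a[-1]
        assert res.crosstab.to_numpy().max(axis=1).sum() == 40  # pure clusters

    def test_wss_nonincreasing_in_k(self, rng):
        X = rng.normal(0, 1, (50, 3))
        wss = [kmeans_cluster(X, k, seed=0, n_restarts=25).total_within_ss
               for k in (2, 3, 4, 5)]
        assert all(b <= a + 1e-9 for a, b in zip(wss, wss[1:]))

    def test_matches_exhaustive_partition_oracle(self, rng):
        for n, k in ((8, 2), (8, 3), (12, 2)):
            X = rng.normal(0, 1, (n, 3))
            # unstructured noise has many near-tied partitions; a generous
            # restart budget lets Lloyd reach the global optimum at this size
            res = kmeans_cluster(X, k, seed=0, n_restarts=200)
            Z = (X - X.mean(axis=0)) / X.std(axis=0)
            assert res.total_within_ss == pytest.approx(
                brute_force_kmeans(Z, k), rel=1e-6)

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(rng.normal(0, 1, (4, 3)), k=5)

    def test_crosstab_row_sums_are_class_counts(self, small_sim):
        hair = small_sim["hair"]
        feats = hair[["elevation_m", "d13C", "d15N"]].to_numpy(float)
        res = kmeans_cluster(feats, 4, seed=0, land_class=hair["land_class"].to_numpy())
        counts = hair["land_class"].value_counts()
        for cls, row in res.crosstab.iterrows():
            assert row.sum() == counts[cls]


class TestSelectK:
    def test_three_separated_blobs(self, rng):
        centers = np.array([[0, 0, 0], [10, 10, 10], [-10, 10, 0]], dtype=float)
        X = np.vstack([c + rng.normal(0, 1, (30, 3)) for c in centers])
        k, diag = select_k(X, k_max=8, seed=0)
        assert k == 3
        assert len(diag["wss"]) == 7  # elbow curve reported

    def test_k_within_bounds(self, rng):
        X = rng.normal(0, 1, (40, 3))
        k, _ = select_k(X, k_max=6, seed=0)
        assert 2 <= k <= 6

    def test_invariant_to_row_duplication(self, rng):
        centers = np.array([[0, 0, 0], [8, 8, 8]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.5, (15, 3)) for c in centers])
        k1, _ = select_k(X, k_max=5, seed=0)
        k2, _ = select_k(np.vstack([X, X]), k_max=5, seed=0)
        assert k1 == k2

    def test_k_max_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="k_max"):
            select_k(rng.normal(0, 1, (5, 3)), k_max=5)


class TestFitSmooth:
    def test_linear_data_collapses_to_ols_line(self, rng):
        x = np.sort(rng.uniform(0, 10, 60))
        y = -1.5 * x + 4.0
        fit = fit_smooth(x, y)
        assert fit.effective_df <= 1.05
        line = 4.0 - 1.5 * fit.grid_x
        np.testing.assert_allclose(fit.grid_fit, line, atol=1e-6)

    def test_sine_recovery_rmse(self, rng):
        x = np.sort(rng.uniform(0, 2 * np.pi, 200))
        y = np.sin(x) + rng.normal(0, 0.1, 200)
        fit = fit_smooth(x, y)
        rmse = np.sqrt(np.mean((fit.fitted - np.sin(x)) ** 2))
        assert rmse < 0.1
        assert fit.p_value < 1e-6

    def test_deviance_bounds_and_beats_ols(self, rng):
        x = np.sort(rng.uniform(0, 10, 100))
        y = np.cos(x) + rng.normal(0, 0.3, 100)
        fit = fit_smooth(x, y)
        assert 0.0 <= fit.deviance_explained <= 1.0
        assert fit.deviance_explained >= ols(x, y).r_squared - 1e-12
        assert 1.0 <= fit.effective_df <= fit.basis_dim - 1

    def test_deviance_nondecreasing_with_basis_dim(self, rng):
        x = np.sort(rng.uniform(0, 2 * np.pi, 150))
        y = np.sin(x) + rng.normal(0, 0.2, 150)
        devs = [fit_smooth(x, y, basis_dim=b).deviance_explained
                for b in (6, 8, 10, 12)]
        assert all(b >= a - 0.01 for a, b in zip(devs, devs[1:]))

    def test_constant_y_degenerate_flag(self, rng):
        x = np.sort(rng.uniform(0, 10, 40))
        fit = fit_smooth(x, np.full(40, 3.0))
        assert fit.degenerate
        assert fit.deviance_explained == 0.0

    def test_few_distinct_x_reduces_basis_with_warning(self, rng):
        x = np.repeat(np.arange(6.0), 5)
        y = x**2 + rng.normal(0, 0.1, 30)
        with pytest.warns(UserWarning, match="distinct"):
            fit = fit_smooth(x, y, basis_dim=10)
        assert fit.basis_dim == 6

    def test_linear_term_matches_ols_f_test(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.8 * x + rng.normal(0, 1, 50)
        lin = fit_linear_term(x, y)
        reg = ols(x, y)
        # classical identity: F = t^2 = r^2 (n-2) / (1 - r^2)
        f_expected = reg.r_squared * 48 / (1 - reg.r_squared)
        assert lin.f_value == pytest.approx(f_expected, rel=1e-10)
        assert lin.effective_df == 1.0


def hair_like_table(rng, n=120):
    dates = pd.date_range("2009-02-15", "2009-04-30")
    elev = rng.uniform(20, 400, n)
    lam = 2.5 - elev / 400.0
    base_C = rng.normal(-28, 0.7, n)
    base_N = rng.normal(5, 1.0, n)
    d13C = base_C + lam * 1.0 + rng.normal(0, 0.2, n)
    d15N = base_N + lam * 3.4 + rng.normal(0, 0.2, n)
    return pd.DataFrame({
        "d13C": d13C, "d15N": d15N,
        "corr_d13C": d13C - base_C, "corr_d15N": d15N - base_N,
        "elevation_m": elev,
        "date": rng.choice(dates, n),
        "land_class": rng.choice(list("ABCDEFG"), n),
    })


class TestCompareSignal:
    def test_constant_baseline_leaves_r_squared_unchanged(self, rng):
        tab = hair_like_table(rng)
        tab["corr_d13C"] = tab["d13C"] - 3.0
        tab["corr_d15N"] = tab["d15N"] + 2.0
        rep = compare_signal(tab, tab, covariates=("elevation_m",), seed=0)
        assert rep.corrected.r_squared == pytest.approx(
            rep.uncorrected.r_squared, abs=1e-12)

    def test_report_shape_contract(self, rng):
        tab = hair_like_table(rng)
        rep = compare_signal(tab, tab, covariates=("date", "elevation_m"), seed=0)
        for ev in (rep.uncorrected, rep.corrected):
            assert 0 <= ev.r_squared <= 1
            assert ev.k >= 2
            assert set(ev.smooths) == {("d13C", "date"), ("d15N", "date"),
                                       ("d13C", "elevation_m"),
                                       ("d15N", "elevation_m")}
            assert set(ev.linear_terms) == set(ev.smooths)
        assert "r_squared" in rep.improved

    def test_spatial_baseline_improves_r_squared(self, rng):
        tab = hair_like_table(rng)
        rep = compare_signal(tab, tab, covariates=(), seed=0)
        assert rep.improved["r_squared"]

    def test_misaligned_tables_rejected(self, rng):
        tab = hair_like_table(rng)
        with pytest.raises(ValueError, match="row-aligned"):
            compare_signal(tab, tab.iloc[:-1], covariates=())


class TestQualitativeSmoothSharpening:
    def test_corrected_smooth_f_values_mostly_exceed_uncorrected(self):
        """Baseline deduction removes spatial noise, so smooth-term F values
        against date/elevation/weather axes should mostly rise; pooled over
        three synthetic replicates the majority must improve."""
        import dataclasses

        from isobase.pipeline import PipelineConfig, run_pipeline
        from isobase.synthetic import SimulationConfig

        wins, total = 0, 0
        for seed in (1, 2, 3):
            cfg = PipelineConfig(simulation=SimulationConfig(seed=seed),
                                 out_dir=f"scratch/qualF_{seed}", seed=seed)
            rep = run_pipeline(cfg)["hair_report"]
            for key, fit in rep.corrected.smooths.items():
                total += 1
                wins += fit.f_value > rep.uncorrected.smooths[key].f_value
        assert wins > total / 2
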