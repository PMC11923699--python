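import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import geofalter as gf
from geofalter.covariates import DesignMatrix, build_lagged_column, standardize
from geofalter.model import scan_lags


class TestExpCorrelation:
    def test_unit_at_zero_distance(self):
        assert gf.exp_correlation(0.0, 7.3) == 1.0

    def test_value_at_three_phi_is_about_005(self):
        assert gf.exp_correlation(3 * 18.28, 18.28) == pytest.approx(0.0498, abs=5e-4)

    def test_half_correlation_at_phi_log2(self):
        phi = 12.5
        assert gf.exp_correlation(phi * np.log(2.0), phi) == pytest.approx(0.5)

    def test_strictly_decreasing_in_distance(self):
        u = np.linspace(0, 300, 200)
        vals = gf.exp_correlation(u, 25.0)
        assert np.all(np.diff(vals) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            gf.exp_correlation(-1.0, 10.0)


class TestPracticalRange:
    @pytest.mark.parametrize(
        "phi,expected", [(32.17, 96.51), (18.28, 54.84), (1.0, 3.0)]
    )
    def test_three_phi_rule(self, phi, expected):
        assert gf.practical_range(phi) == pytest.approx(expected)

    def test_exact_option_solves_for_005(self):
        phi = 20.0
        r = gf.practical_range(phi, exact=True)
        assert gf.exp_correlation(r, phi) == pytest.approx(0.05)


class TestBuildCovariance:
    def test_same_cluster_shares_full_spatial_variance(self):
        params = gf.GeoModelParams(0.0, np.zeros(1), 0.15, 18.0, 2.0)
        cov = gf.build_covariance(np.array([[0.0, 0.0]]), np.array([0, 0]), params)
        assert cov[0, 1] == pytest.approx(0.15)
        assert cov[0, 0] == pytest.approx(2.15)

    def test_matches_hand_built_matrix_three_clusters(self):
        """Brute-force oracle: 3 clusters x 2 individuals, element by
        element."""
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 30.0]])
        idx = np.array([0, 0, 1, 1, 2, 2])
        s2, phi, w2 = 0.4, 15.0, 1.1
        params = gf.GeoModelParams(0.0, np.zeros(1), s2, phi, w2)
        cov = gf.build_covariance(xy, idx, params)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        for a in range(6):
            for b in range(6):
                expected = s2 * np.exp(-d[idx[a], idx[b]] / phi) + w2 * (a == b)
                assert cov[a, b] == pytest.approx(expected, abs=1e-12)

    def test_long_range_limit_saturates_offdiagonals(self):
        xy = np.array([[0.0, 0.0], [100.0, 100.0]])
        idx = np.array([0, 1])
        params = gf.GeoModelParams(0.0, np.zeros(1), 0.3, 1e9, 0.5)
        cov = gf.build_covariance(xy, idx, params)
        assert cov[0, 1] == pytest.approx(0.3, rel=1e-6)


class TestLogLikelihood:
    def _instance(self, rng, n_clusters, max_per_cluster=4):
        xy = rng.uniform(0, 100, size=(n_clusters, 2))
        sizes = rng.integers(1, max_per_cluster + 1, size=n_clusters)
        idx = np.repeat(np.arange(n_clusters), sizes)
        n = len(idx)
        X = rng.normal(size=(n, 2))
        params = gf.GeoModelParams(
            alpha=rng.normal(),
            beta=rng.normal(size=2),
            sigma2=rng.uniform(0.05, 1.0),
            phi=rng.uniform(5.0, 60.0),
            omega2=rng.uniform(0.2, 3.0),
        )
        y = rng.normal(size=n)
        return y, X, xy, idx, params

    def test_agrees_with_dense_mvn_on_100_random_instances(self):
        """Blocked likelihood vs dense multivariate-normal oracle to 1e-8
        on instances with up to 50 individuals."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            y, X, xy, idx, params = self._instance(rng, int(rng.integers(2, 13)))
            ll = gf.log_likelihood(y, X, xy, idx, params)
            cov = gf.build_covariance(xy, idx, params)
            dense = multivariate_normal.logpdf(
                y, mean=params.alpha + X @ params.beta, cov=cov
            )
            assert ll == pytest.approx(dense, abs=1e-8)

    def test_independence_limit_sums_univariate_densities(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        xy = rng.uniform(0, 50, size=(6, 2))
        idx = np.repeat(np.arange(6), 5)
        params = gf.GeoModelParams(0.3, np.zeros(0), 0.0, 10.0, 1.7)
        ll = gf.log_likelihood(y, np.empty((30, 0)), xy, idx, params)
        from scipy.stats import norm

        expected = norm.logpdf(y, loc=0.3, scale=np.sqrt(1.7)).sum()
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        y, X, xy, idx, params = self._instance(rng, 8)
        ll = gf.log_likelihood(y, X, xy, idx, params)
        shifted = gf.GeoModelParams(
            params.alpha + 5.0, params.beta, params.sigma2, params.phi,
            params.omega2,
        )
        ll2 = gf.log_likelihood(y + 5.0, X, xy, idx, shifted)
        assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_invariant_to_cluster_relabeling_and_permutation(self):
        rng = np.random.default_rng(3)
        y, X, xy, idx, params = self._instance(rng, 7)
        ll = gf.log_likelihood(y, X, xy, idx, params)
        perm = rng.permutation(len(y))
        relabel = rng.permutation(len(xy))
        inv = np.argsort(relabel)
        ll2 = gf.log_likelihood(
            y[perm], X[perm], xy[relabel], inv[idx][perm], params
        )
        assert ll2 == pytest.approx(ll, abs=1e-8)


class TestFitMLE:
    def test_null_model_estimates_near_zero_effects(self):
        rng = np.random.default_rng(4)
        c, m = 80, 8
        xy = rng.uniform(0, 300, size=(c, 2))
        idx = np.repeat(np.arange(c), m)
        X = rng.normal(size=(c * m, 1))
        y = rng.normal(0.0, 1.0, size=c * m)  # sigma2 = 0, beta = 0
        fit = gf.fit_mle(y, X, xy, idx, check_identifiability=False)
        ci = fit.conf_int.loc["x0"]
        assert ci["ci_lower"] <= 0.0 <= ci["ci_upper"]
        assert fit.params.sigma2 < 0.1

    def test_aic_matches_definition(self, small_survey):
        d = small_survey.data
        fit = gf.fit_mle(
            d.z("haz"), small_survey.design.values, d.cluster_xy,
            d.cluster_index, n_restarts=1, check_identifiability=False,
        )
        assert fit.aic == pytest.approx(
            2 * fit.n_free_params - 2 * fit.log_likelihood
        )
        # k = intercept + 2 covariates + 3 covariance parameters
        assert fit.n_free_params == 6

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            gf.fit_mle(
                np.zeros(3), np.zeros((3, 1)), np.zeros((1, 2)), np.zeros(3, int)
            )

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        xy = rng.uniform(0, 50, (4, 2))
        idx = np.repeat(np.arange(4), 5)
        with pytest.raises(ValueError, match="rank"):
            gf.fit_mle(rng.normal(size=20), X, xy, idx)

    def test_variance_cis_are_asymmetric_back_transformed(self, small_survey):
        d = small_survey.data
        fit = gf.fit_mle(
            d.z("haz"), small_survey.design.values, d.cluster_xy,
            d.cluster_index, n_restarts=1, check_identifiability=False,
        )
        row = fit.conf_int.loc["omega2"]
        assert row["ci_lower"] > 0
        assert row["ci_lower"] <= row["estimate"] <= row["ci_upper"]
        # log-scale construction: upper/est ratio exceeds est/lower symmetry
        up = row["ci_upper"] / row["estimate"]
        down = row["estimate"] / row["ci_lower"]
        assert up == pytest.approx(down, rel=1e-6)

    def test_nonspatial_variant_has_one_fewer_parameter(self, small_survey):
        d = small_survey.data
        fit = gf.fit_mle(
            d.z("haz"), small_survey.design.values, d.cluster_xy,
            d.cluster_index, spatial=False, n_restarts=1,
            check_identifiability=False,
        )
        assert not fit.spatial
        assert not np.isfinite(fit.params.phi)
        assert fit.n_free_params == 5

    def test_flat_spatial_signal_flags_phi_and_attaches_fallback(self):
        """Data with no spatial structure: phi reported non-identifiable
        and a compound-symmetry (iid cluster effects) fit attached."""
        rng = np.random.default_rng(6)
        c, m = 60, 6
        xy = rng.uniform(0, 400, size=(c, 2))
        idx = np.repeat(np.arange(c), m)
        y = -0.5 + rng.normal(0, 1.2, size=c * m)  # pure nugget
        fit = gf.fit_mle(y, np.empty((c * m, 0)), xy, idx)
        assert not fit.phi_identifiable
        assert fit.fallback is not None
        assert not fit.fallback.spatial


class TestScanLags:
    def _base(self, survey):
        return survey.design

    def test_single_lag_scan_selects_it(self, small_survey):
        d = small_survey.data
        xy = d.individual_xy
        series = small_survey.stack.extract_monthly("spei", xy[:, 0], xy[:, 1])
        cols = {1: build_lagged_column(series, d.birth_month, 1)}
        scan = scan_lags(
            d.z("haz"), small_survey.design, d.cluster_xy, d.cluster_index,
            "spei", cols,
        )
        assert scan.selected_lag == 1
        assert len(scan.table) == 1

    def test_constant_covariate_gives_flat_aic_and_shortest_lag(self, small_survey):
        d = small_survey.data
        n = d.n_individuals
        const = d.cluster_xy[d.cluster_index, 0]  # varies by place, not time
        cols = {lag: const.copy() for lag in (1, 2, 3)}
        scan = scan_lags(
            d.z("haz"), small_survey.design, d.cluster_xy, d.cluster_index,
            "spei", cols,
        )
        aics = scan.table["aic"].to_numpy()
        assert np.ptp(aics) < 0.05  # identical up to optimizer tolerance
        assert scan.selected_lag == 1

    def test_failed_lag_reported_and_scan_continues(self, small_survey):
        d = small_survey.data
        xy = d.individual_xy
        series = small_survey.stack.extract_monthly("spei", xy[:, 0], xy[:, 1])
        good = build_lagged_column(series, d.birth_month, 2)
        bad = np.full(d.n_individuals, np.nan)
        scan = scan_lags(
            d.z("haz"), small_survey.design, d.cluster_xy, d.cluster_index,
            "spei", {1: bad, 2: good},
        )
        assert scan.selected_lag == 2
        assert 1 in scan.failures
        assert not scan.table.set_index("lag").loc[1, "ok"]


class TestVariogram:
    def test_identical_residuals_give_zero_semivariance(self):
        xy = np.random.default_rng(7).uniform(0, 100, size=(10, 2))
        vg = gf.empirical_variogram(np.full(10, 2.5), xy, n_bins=4)
        occupied = vg.pair_counts > 0
        assert np.all(vg.semivariance[occupied] == 0.0)

    def test_four_clusters_match_pencil_and_paper(self):
        """Hand-computed oracle on a 2x2 km square with residuals
        (0, 1, 3, 6)."""
        xy = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        r = np.array([0.0, 1.0, 3.0, 6.0])
        # pairs at distance 2: (0,1)=0.5, (0,2)=4.5, (1,3)=12.5, (2,3)=4.5
        # pairs at distance 2*sqrt(2): (0,3)=18, (1,2)=2
        vg = gf.empirical_variogram(r, xy, bins=np.array([1.5, 2.5, 3.5]))
        assert vg.semivariance[0] == pytest.approx((0.5 + 4.5 + 12.5 + 4.5) / 4)
        assert vg.semivariance[1] == pytest.approx((18.0 + 2.0) / 2)
        assert vg.pair_counts.tolist() == [4, 2]

    def test_empty_bin_flagged_not_dropped(self):
        xy = np.array([[0.0, 0.0], [100.0, 0.0]])
        vg = gf.empirical_variogram(
            np.array([1.0, 2.0]), xy, bins=np.array([0.0, 10.0, 150.0])
        )
        assert vg.pair_counts[0] == 0
        assert np.isnan(vg.semivariance[0])
        assert vg.pair_counts[1] == 1

    def test_pure_nugget_variogram_stays_inside_permutation_envelope(self):
        """With sigma2 = 0 the variogram is flat: each replicate's curve
        should lie within the independence envelope in >= 90% of 20
        replicates."""
        rng = np.random.default_rng(8)
        inside = 0
        for rep in range(20):
            xy = rng.uniform(0, 200, size=(60, 2))
            r = rng.normal(size=60)  # no spatial structure at all
            vg = gf.empirical_variogram(
                r, xy, n_bins=5, n_permutations=499, seed=rep
            )
            ok = vg.pair_counts > 0
            if np.all(
                (vg.semivariance[ok] >= vg.envelope_low[ok])
                & (vg.semivariance[ok] <= vg.envelope_high[ok])
            ):
                inside += 1
        assert inside >= 18


def test_likelihood_parameter_recovery_smoke(spei_only_config):
    """Single-replicate sanity check that the MLE lands near the truth
    (the full 50-replicate bias/coverage study runs in the acceptance
    suite)."""
    import dataclasses

    cfg = dataclasses.replace(spei_only_config, seed=77)
    sv = gf.simulate_survey(cfg)
    d = sv.data
    fit = gf.fit_mle(
        d.z("haz"), sv.design.values, d.cluster_xy, d.cluster_index,
        check_identifiability=False,
    )
    assert fit.converged
    assert fit.params.omega2 == pytest.approx(2.02, rel=0.15)
    assert fit.params.sigma2 == pytest.approx(0.15, rel=0.6)
    assert abs(fit.params.alpha - (-1.23)) < 0.15
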