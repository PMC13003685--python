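"""CTCRW fitting: Kalman likelihood oracle, smoothing, imputation, rerouting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from divetrace import synthetic, track
from divetrace.projection import geo_to_plane
from divetrace.track import _transition4, _initial_state, kalman_filter


def _sim_obs(beta=1.0, sigma=4.0, hours=120.0, rate_per_day=48.0,
             ellipse_m=800.0, seed=0):
    path = synthetic.simulate_ctcrw_track(beta, sigma, hours, dt_h=1 / 60, seed=seed)
    obs = synthetic.degrade_to_observations(path, rate_per_day, ellipse_m, seed=seed + 1)
    return path, obs


def brute_force_loglik(beta, sigma, t_h, xy, R):
    """Joint-Gaussian likelihood of the stacked observation vector.

    Builds the full prior mean and covariance of the states by propagating
    the initial distribution, then evaluates the 2n-dimensional Gaussian
    density directly.  Independent of the Kalman recursion.
    """
    n = len(t_h)
    H = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
    m0, P0 = _initial_state(beta, sigma, xy[0])
    means = [m0]
    covs = np.empty((n, 4, 4))
    covs[0] = P0
    As = [None]
    for i in range(1, n):
        A, Q = _transition4(beta, sigma, t_h[i] - t_h[i - 1])
        means.append(A @ means[-1])
        covs[i] = A @ covs[i - 1] @ A.T + Q
        As.append(A)
    # Cross-covariances Cov(s_i, s_j) = P_i * Phi(i->j)^T for i < j.
    big = np.zeros((n, 4, n, 4))
    for i in range(n):
        big[i, :, i, :] = covs[i]
        Phi = np.eye(4)
        for j in range(i + 1, n):
            Phi = As[j] @ Phi
            c = covs[i] @ Phi.T
            big[i, :, j, :] = c
            big[j, :, i, :] = c.T
    Hbig = np.zeros((2 * n, 4 * n))
    for i in range(n):
        Hbig[2 * i:2 * i + 2, 4 * i:4 * i + 4] = H
    S = Hbig @ big.reshape(4 * n, 4 * n) @ Hbig.T
    for i in range(n):
        S[2 * i:2 * i + 2, 2 * i:2 * i + 2] += R[i]
    mu = Hbig @ np.concatenate(means)
    return multivariate_normal.logpdf(xy.reshape(-1), mu, S)


class TestKalmanLikelihood:
    @pytest.mark.parametrize("n_obs,seed", [(4, 0), (7, 1), (10, 2)])
    def test_matches_bruteforce_joint_gaussian(self, n_obs, seed):
        rng = np.random.default_rng(seed)
        t_h = np.cumsum(rng.uniform(0.2, 3.0, n_obs))
        xy = np.cumsum(rng.normal(0, 2.0, (n_obs, 2)), axis=0)
        R = np.array([np.diag(rng.uniform(0.01, 0.3, 2)) for _ in range(n_obs)])
        for beta, sigma in [(0.5, 2.0), (2.0, 6.0)]:
            kf = kalman_filter(beta, sigma, t_h, xy, R)["loglik"]
            bf = brute_force_loglik(beta, sigma, t_h, xy, R)
            assert kf == pytest.approx(bf, abs=1e-6)

    def test_doubling_ellipses_lowers_likelihood(self):
        _, obs = _sim_obs(seed=3)
        fit = track.fit_ctcrw(obs)
        t_h = fit._t_hours(fit.obs_time)
        ll1 = kalman_filter(fit.beta, fit.sigma, t_h, fit.obs_xy_km, fit.obs_R_km2)["loglik"]
        ll2 = kalman_filter(fit.beta, fit.sigma, t_h, fit.obs_xy_km,
                            fit.obs_R_km2 * 4.0)["loglik"]  # axes doubled
        assert ll2 < ll1

    def test_smoother_variance_below_filter_variance(self):
        _, obs = _sim_obs(seed=4)
        fit = track.fit_ctcrw(obs)
        t_h = fit._t_hours(fit.obs_time)
        filt = kalman_filter(fit.beta, fit.sigma, t_h, fit.obs_xy_km, fit.obs_R_km2)
        from divetrace.track import _rts_smooth
        ms, Ps = _rts_smooth(fit.beta, fit.sigma, filt)
        diag_f = np.diagonal(filt["Pf"], axis1=1, axis2=2)
        diag_s = np.diagonal(Ps, axis1=1, axis2=2)
        assert (diag_s <= diag_f + 1e-9).all()


class TestPrefilter:
    def test_clean_track_untouched_and_idempotent(self):
        _, obs = _sim_obs(ellipse_m=200.0, seed=5)
        once = track.prefilter_locations(obs)
        assert len(once) == len(obs)
        twice = track.prefilter_locations(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_planted_outlier_removed(self):
        _, obs = _sim_obs(ellipse_m=200.0, seed=6)
        bad = obs.iloc[len(obs) // 2].copy()
        bad["lon"] += 1.0  # ~100 km spike between 30-min neighbors
        obs2 = pd.concat([obs, bad.to_frame().T], ignore_index=True)
        obs2["lon"] = obs2["lon"].astype(float)
        obs2["lat"] = obs2["lat"].astype(float)
        out = track.prefilter_locations(obs2)
        assert len(out) == len(obs)
        assert not np.any(np.isclose(out["lon"].to_numpy(), bad["lon"]))

    def test_too_few_locations_rejected(self):
        _, obs = _sim_obs(seed=7)
        with pytest.raises(ValueError):
            track.prefilter_locations(obs.iloc[:2])


class TestFitAndPredict:
    def test_near_noiseless_dense_observations_recover_path(self):
        # Noise-free fixes taken exactly at path grid times, every 5 min.
        path = synthetic.simulate_ctcrw_track(1.0, 4.0, 72.0, dt_h=1 / 60, seed=8)
        sub = slice(0, None, 5)
        obs = pd.DataFrame({
            "time": path.time[sub], "lon": path.lon[sub], "lat": path.lat[sub],
            "semi_major_m": 1.0, "semi_minor_m": 1.0, "orientation_deg": 0.0,
        })
        fit = track.fit_ctcrw(obs)
        pred = track.predict_positions(fit, obs["time"].iloc[10:300])
        t_lon, t_lat = path.interp_geo(pred["time"])
        tx, ty = geo_to_plane(t_lon, t_lat, *fit.center)
        err_m = np.hypot(pred["x_km"] - tx, pred["y_km"] - ty) * 1000.0
        # Error bounded by the 10-m ellipse floor (sigma ~ 4 m), not by the fit.
        assert np.median(err_m) < 4.0

    def test_gap_prediction_more_uncertain_than_at_observations(self):
        _, obs = _sim_obs(seed=10)
        fit = track.fit_ctcrw(obs)
        t_obs = pd.Timestamp(obs["time"].iloc[50])
        gap_mid = obs["time"].iloc[50] + (obs["time"].iloc[51] - obs["time"].iloc[50]) / 2
        pred = track.predict_positions(fit, [t_obs, gap_mid])
        assert (pred["ellipse95_semi_major_m"].iloc[1]
                > pred["ellipse95_semi_major_m"].iloc[0])

    def test_extrapolation_flagged(self):
        _, obs = _sim_obs(seed=11)
        fit = track.fit_ctcrw(obs)
        far = pd.Timestamp(obs["time"].iloc[-1]) + pd.Timedelta(hours=12)
        pred = track.predict_positions(fit, [far])
        assert bool(pred["extrapolated"].iloc[0])


class TestImputation:
    def test_same_seed_identical(self):
        _, obs = _sim_obs(seed=12)
        fit = track.fit_ctcrw(obs)
        times = pd.date_range(obs["time"].iloc[0], obs["time"].iloc[-1], periods=40)
        a = track.impute_tracks(fit, times, K=5, seed=1)
        b = track.impute_tracks(fit, times, K=5, seed=1)
        assert np.array_equal(a.lon, b.lon)

    def test_spread_larger_in_gaps(self):
        _, obs = _sim_obs(seed=13)
        fit = track.fit_ctcrw(obs)
        t_obs = pd.DatetimeIndex(obs["time"].iloc[40:60])
        gaps = t_obs[:-1] + (t_obs[1:] - t_obs[:-1]) / 2
        imp_obs = track.impute_tracks(fit, t_obs, K=30, seed=2)
        imp_gap = track.impute_tracks(fit, gaps, K=30, seed=2)
        sd_obs = np.median(imp_obs.x_km.std(axis=0, ddof=1))
        sd_gap = np.median(imp_gap.x_km.std(axis=0, ddof=1))
        assert sd_gap > sd_obs

    def test_k_below_two_rejected(self):
        _, obs = _sim_obs(seed=14)
        fit = track.fit_ctcrw(obs)
        with pytest.raises(ValueError):
            track.impute_tracks(fit, obs["time"].iloc[:5], K=1)


class TestRerouteLand:
    def test_offshore_point_unchanged(self, small_rasters):
        bathy, _ = small_rasters
        pts = pd.DataFrame({"lon": [-155.5], "lat": [22.5]})
        out = track.reroute_land(pts, bathy)
        assert out["rerouted_km"].iloc[0] == 0.0
        assert out["lon"].iloc[0] == -155.5

    def test_island_center_relocated_beyond_isobath(self, small_rasters):
        bathy, _ = small_rasters
        pts = pd.DataFrame({"lon": [-157.0, -157.05], "lat": [20.8, 20.75]})
        out = track.reroute_land(pts, bathy, isobath_m=20.0)
        assert (out["rerouted_km"] > 0).all()
        from divetrace.covariates import extract_at
        depths = extract_at(bathy, out["lon"].to_numpy(), out["lat"].to_numpy())
        assert (depths >= 20.0).all()
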