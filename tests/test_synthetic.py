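"""Generator contracts: OU track statistics, observation degradation, rasters,
behavior-log truth linkage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from divetrace import synthetic
from divetrace.projection import geo_to_plane, plane_to_geo


class TestProjection:
    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        lon = -157.0 + rng.uniform(-3, 3, 100)
        lat = 20.8 + rng.uniform(-3, 3, 100)
        x, y = geo_to_plane(lon, lat, -157.0, 20.8)
        lon2, lat2 = plane_to_geo(x, y, -157.0, 20.8)
        assert np.allclose(lon, lon2, atol=1e-9)
        assert np.allclose(lat, lat2, atol=1e-9)

    def test_center_distance_exact(self):
        # One degree of latitude from the center = 111.19 km.
        x, y = geo_to_plane(-157.0, 21.8, -157.0, 20.8)
        assert abs(x) < 1e-9
        assert y == pytest.approx(111.195, abs=0.01)


class TestCTCRWTrack:
    def test_large_beta_decorrelates_velocity(self):
        p = synthetic.simulate_ctcrw_track(100.0, 10.0, 50.0, dt_h=0.1, seed=0)
        r = np.corrcoef(p.vx[:-1], p.vx[1:])[0, 1]
        assert abs(r) < 0.05

    def test_velocity_autocorrelation_matches_closed_form(self):
        beta, dt = 1.0, 0.1
        p = synthetic.simulate_ctcrw_track(beta, 4.0, 1000.0, dt_h=dt, seed=2)
        for lag in (1, 5, 10):
            r = np.corrcoef(p.vx[:-lag], p.vx[lag:])[0, 1]
            assert r == pytest.approx(np.exp(-beta * lag * dt), abs=0.05)

    def test_same_seed_identical(self):
        a = synthetic.simulate_ctcrw_track(1.0, 4.0, 24.0, seed=5)
        b = synthetic.simulate_ctcrw_track(1.0, 4.0, 24.0, seed=5)
        assert np.array_equal(a.x_km, b.x_km)
        assert np.array_equal(a.vy, b.vy)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_ctcrw_track(-1.0, 4.0, 24.0)
        with pytest.raises(ValueError):
            synthetic.simulate_ctcrw_track(1.0, 0.0, 24.0)

    def test_speed_is_rayleigh_stationary(self):
        # Stationary OU speed ~ Rayleigh with scale sigma/sqrt(2 beta).
        beta, sigma = 1.0, 4.0
        p = synthetic.simulate_ctcrw_track(beta, sigma, 5000.0, dt_h=0.5, seed=3)
        speed = np.hypot(p.vx, p.vy)[::5][:10000]  # thin for near-independence
        scale = sigma / np.sqrt(2 * beta)
        ks = sps.kstest(speed, "rayleigh", args=(0, scale))
        assert ks.pvalue > 0.01


class TestDegradeToObservations:
    def test_zero_noise_recovers_truth(self):
        p = synthetic.simulate_ctcrw_track(1.0, 4.0, 100.0, seed=1)
        obs = synthetic.degrade_to_observations(p, 24.0, 0.0, seed=2)
        tx, ty = p.interp_plane(obs["time"])
        ox, oy = geo_to_plane(obs["lon"].to_numpy(), obs["lat"].to_numpy(), *p.center)
        # ellipse axes floor at 0 here; positions should match truth closely
        assert np.allclose(ox, tx, atol=1e-6)
        assert np.allclose(oy, ty, atol=1e-6)

    def test_error_statistics(self):
        p = synthetic.simulate_ctcrw_track(1.0, 4.0, 3000.0, dt_h=0.25, seed=4)
        obs = synthetic.degrade_to_observations(p, 100.0, 2000.0, seed=5)
        assert len(obs) > 5000
        tx, ty = p.interp_plane(obs["time"])
        ox, oy = geo_to_plane(obs["lon"].to_numpy(), obs["lat"].to_numpy(), *p.center)
        dx = (ox - tx) * 1000.0
        dy = (oy - ty) * 1000.0
        # Zero-mean within 3 SE.
        for d in (dx, dy):
            assert abs(d.mean()) < 3 * d.std() / np.sqrt(len(d))
        # Mahalanobis^2 wrt the stored ellipse covariances ~ chi-square(2).
        from divetrace.track import ellipse_to_cov_m2
        cov = ellipse_to_cov_m2(obs["semi_major_m"], obs["semi_minor_m"],
                                obs["orientation_deg"])
        inv = np.linalg.inv(cov)
        e = np.stack([dx, dy], axis=1)
        m2 = np.einsum("ni,nij,nj->n", e, inv, e)
        assert np.quantile(m2, 0.95) == pytest.approx(5.99, abs=0.3)

    def test_rate_rejected(self):
        p = synthetic.simulate_ctcrw_track(1.0, 4.0, 24.0, seed=1)
        with pytest.raises(ValueError):
            synthetic.degrade_to_observations(p, 0.0, 100.0)


class TestRasters:
    def test_land_cells_zero_depth_and_flagged(self, small_rasters):
        bathy, env = small_rasters
        land = bathy.to_numpy() == 0.0
        assert land.any() and (~land).any()
        # chl flag covers land on its own (coarser) grid.
        flag0 = env["chl_flag"].isel(time=0)
        on_land = flag0.sel(lon=-157.0, lat=20.8, method="nearest")
        assert int(on_land) == 1

    def test_bathymetry_continuity(self, small_rasters):
        bathy, _ = small_rasters
        z = bathy.to_numpy()
        # Max 4-neighbor difference bounded by the declared gradient bound
        # times the cell size (~2.23 km at this resolution).
        bound = bathy.attrs["max_gradient_m_per_km"] * 2.23 * 1.05
        for diff in (np.abs(np.diff(z, axis=0)), np.abs(np.diff(z, axis=1))):
            assert diff.max() < bound

    def test_same_seed_identical(self):
        a = synthetic.build_rasters((-158, -156, 20, 22), 0.05, seed=3)
        b = synthetic.build_rasters((-158, -156, 20, 22), 0.05, seed=3)
        assert np.array_equal(a[0].to_numpy(), b[0].to_numpy())
        assert a[1].equals(b[1])

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            synthetic.build_rasters((-158, -156, 20, 22), 0.0)


class TestBehaviorLogGeneration:
    def test_truth_linkage_exact(self, small_scenario):
        """Every emitted dive record corresponds to one truth row passing the
        tag thresholds, and counts agree exactly."""
        thr_d, thr_s = small_scenario.config.tag_thresholds
        for aid in small_scenario.behavior_logs:
            recs = small_scenario.behavior_logs[aid]
            truth = small_scenario.truths[aid].true_dive_table
            n_emitted = int((recs["kind"] == "dive").sum())
            passing = (~((truth["depth"] < thr_d) & (truth["duration"] < thr_s))).sum()
            assert n_emitted == passing == truth["emitted_as_dive"].sum()

    def test_minmax_bracket_means_exact(self, small_scenario):
        recs = small_scenario.behavior_logs["Tag001"]
        dives = recs[recs["kind"] == "dive"]
        truth = small_scenario.truths["Tag001"].true_dive_table
        emitted = truth[truth["emitted_as_dive"]]
        assert np.allclose(np.sort(dives["depth"]), np.sort(emitted["depth"]),
                           rtol=1e-12)

    def test_seafloor_plants_within_50m(self, small_scenario):
        for aid, tr in small_scenario.truths.items():
            t = tr.true_dive_table
            sf = t[t["is_near_seafloor"]]
            if len(sf):
                gap = sf["seafloor_depth"] - sf["depth"]
                assert (gap >= 0).all() and (gap <= 50).all()

    def test_no_seafloor_fraction_means_none(self):
        cfg = synthetic.ScenarioConfig(n_animals=1, duration_days=3.0,
                                       frac_seafloor_dives=0.0, seed=21)
        sc = synthetic.simulate_scenario(cfg)
        t = sc.truths["Tag001"].true_dive_table
        assert t["is_near_seafloor"].sum() == 0

    def test_realized_rate_matches_poisson(self):
        cfg = synthetic.ScenarioConfig(n_animals=1, duration_days=30.0,
                                       rate_diel_amplitude=0.0, seed=22)
        sc = synthetic.simulate_scenario(cfg)
        t = sc.truths["Tag001"].true_dive_table
        T = 30.0 * 24.0
        rate = len(t) / T
        expect = cfg.dive_rate_base
        assert abs(rate - expect) <= 3.0 * np.sqrt(expect / T)

    def test_depth_duration_rank_correlation(self):
        cfg = synthetic.ScenarioConfig(n_animals=1, duration_days=30.0,
                                       frac_seafloor_dives=0.0, seed=23)
        sc = synthetic.simulate_scenario(cfg)
        t = sc.truths["Tag001"].true_dive_table
        rho = sps.spearmanr(t["depth"], t["duration"]).statistic
        assert rho == pytest.approx(0.7, abs=0.12)

    def test_scenario_determinism(self):
        cfg = synthetic.ScenarioConfig(n_animals=2, duration_days=2.0, seed=9)
        a = synthetic.simulate_scenario(cfg)
        b = synthetic.simulate_scenario(cfg)
        for aid in a.behavior_logs:
            pd.testing.assert_frame_equal(a.behavior_logs[aid], b.behavior_logs[aid])
            pd.testing.assert_frame_equal(a.observations[aid], b.observations[aid])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthetic.ScenarioConfig(frac_seafloor_dives=1.5)
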