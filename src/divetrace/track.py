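"""Continuous-time correlated random walk (CTCRW) track modeling.

The CTCRW is a state-space movement model in which each planar axis carries a
position and an Ornstein-Uhlenbeck velocity: dv = -beta v dt + sigma dW, with
position the time integral of velocity.  Irregularly timed locations with
anisotropic error ellipses are assimilated with a Kalman filter using the
exact Gaussian transition for each time step, so the likelihood is available
in closed form and is maximized over (beta, sigma).  An RTS smoother gives
position estimates with uncertainty at arbitrary times (e.g., dive record
times), and forward-filtering backward-sampling draws multiple imputations of
the full path for propagating location uncertainty into downstream spatial
analyses.

All model math is planar, in kilometers, on an azimuthal equidistant
projection centered on the observed track; geographic coordinates are
restored on output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .projection import geo_to_plane, plane_to_geo
from .synthetic import CHI2_95_2D, _ou_transition

_H = np.array([[1.0, 0.0, 0.0, 0.0],
               [0.0, 0.0, 1.0, 0.0]])

#: Prior SD on initial position, km (weakly informative around the first fix).
_P0_POS_SD_KM = 100.0

#: Floor on ellipse axes, meters (degenerate / missing ellipse protection).
ELLIPSE_FLOOR_M = 10.0

#: Default 95% circular error applied to GPS fixes lacking an ellipse, m.
GPS_ELLIPSE95_M = 50.0


def ellipse_to_cov_m2(semi_major_m, semi_minor_m, orientation_deg) -> np.ndarray:
    """Convert 95% error ellipses to 2x2 (east, north) covariances in m^2.

    Stored ellipse axes are treated as 95% coverage radii of a bivariate
    Gaussian (so 1-sigma axes are semi_axis / sqrt(5.991)); orientation is
    the azimuth of the semi-major axis, degrees clockwise from north.
    """
    a = np.maximum(np.asarray(semi_major_m, float), ELLIPSE_FLOOR_M) / np.sqrt(CHI2_95_2D)
    b = np.maximum(np.asarray(semi_minor_m, float), ELLIPSE_FLOOR_M) / np.sqrt(CHI2_95_2D)
    th = np.deg2rad(np.asarray(orientation_deg, float))
    ue = np.sin(th)
    un = np.cos(th)
    cov = np.empty(np.broadcast(a, th).shape + (2, 2))
    cov[..., 0, 0] = a ** 2 * ue ** 2 + b ** 2 * un ** 2
    cov[..., 1, 1] = a ** 2 * un ** 2 + b ** 2 * ue ** 2
    cov[..., 0, 1] = cov[..., 1, 0] = (a ** 2 - b ** 2) * ue * un
    return cov


def _transition4(beta: float, sigma: float, dt_h: float):
    A2, Q2 = _ou_transition(beta, sigma, dt_h)
    A = np.zeros((4, 4))
    Q = np.zeros((4, 4))
    A[:2, :2] = A2
    A[2:, 2:] = A2
    Q[:2, :2] = Q2
    Q[2:, 2:] = Q2
    return A, Q


def _initial_state(beta: float, sigma: float, xy0: np.ndarray):
    m0 = np.array([xy0[0], 0.0, xy0[1], 0.0])
    var_v = sigma ** 2 / (2.0 * beta)
    P0 = np.diag([_P0_POS_SD_KM ** 2, var_v, _P0_POS_SD_KM ** 2, var_v])
    return m0, P0


def kalman_filter(beta: float, sigma: float, t_h: np.ndarray, xy_km: np.ndarray,
                  R_km2: np.ndarray, observed: np.ndarray | None = None):
    """Run the CTCRW Kalman filter over a merged timeline.

    ``observed`` marks which timeline entries carry a location (all, by
    default).  Returns a dict with the log-likelihood and per-step filtered
    and one-step-ahead predicted means/covariances (needed by the smoother
    and backward sampler).
    """
    n = len(t_h)
    if observed is None:
        observed = np.ones(n, dtype=bool)
    first_obs = int(np.flatnonzero(observed)[0])
    m, P = _initial_state(beta, sigma, xy_km[first_obs])

    mf = np.empty((n, 4))
    Pf = np.empty((n, 4, 4))
    mp = np.empty((n, 4))
    Pp = np.empty((n, 4, 4))
    loglik = 0.0
    I4 = np.eye(4)
    for i in range(n):
        if i > 0:
            dt = t_h[i] - t_h[i - 1]
            A, Q = _transition4(beta, sigma, max(dt, 1e-9))
            m = A @ m
            P = A @ P @ A.T + Q
        mp[i], Pp[i] = m, P
        if observed[i]:
            y = xy_km[i] - _H @ m
            S = _H @ P @ _H.T + R_km2[i]
            Sinv = np.linalg.inv(S)
            K = P @ _H.T @ Sinv
            m = m + K @ y
            KH = I4 - K @ _H
            P = KH @ P @ KH.T + K @ R_km2[i] @ K.T  # Joseph form
            sign, logdet = np.linalg.slogdet(S)
            loglik += -0.5 * (y @ Sinv @ y + logdet + 2.0 * np.log(2.0 * np.pi))
        mf[i], Pf[i] = m, P
    return {"loglik": loglik, "mf": mf, "Pf": Pf, "mp": mp, "Pp": Pp,
            "t_h": t_h, "observed": observed}


def _rts_smooth(beta: float, sigma: float, filt: dict):
    t_h, mf, Pf, mp, Pp = (filt["t_h"], filt["mf"], filt["Pf"],
                           filt["mp"], filt["Pp"])
    n = len(t_h)
    ms = mf.copy()
    Ps = Pf.copy()
    for i in range(n - 2, -1, -1):
        dt = t_h[i + 1] - t_h[i]
        A, _ = _transition4(beta, sigma, max(dt, 1e-9))
        J = Pf[i] @ A.T @ np.linalg.inv(Pp[i + 1])
        ms[i] = mf[i] + J @ (ms[i + 1] - mp[i + 1])
        Ps[i] = Pf[i] + J @ (Ps[i + 1] - Pp[i + 1]) @ J.T
    return ms, Ps


@dataclass
class CTCRWFit:
    """A fitted CTCRW movement model for one deployment."""

    beta: float            # 1/hour
    sigma: float           # km/hour^1.5
    error_inflation: float
    loglik: float
    center: tuple[float, float]
    obs_time: pd.DatetimeIndex
    obs_xy_km: np.ndarray
    obs_R_km2: np.ndarray

    def _t_hours(self, times) -> np.ndarray:
        return (pd.DatetimeIndex(times) - self.obs_time[0]).total_seconds().to_numpy() / 3600.0

    def _merged_timeline(self, extra_times):
        """Union of observation and query times; returns (t_h, observed, query_idx)."""
        t_obs = self._t_hours(self.obs_time)
        t_new = self._t_hours(extra_times)
        t_all = np.concatenate([t_obs, t_new])
        obs_flag = np.concatenate([np.ones(len(t_obs), bool), np.zeros(len(t_new), bool)])
        order = np.argsort(t_all, kind="stable")
        t_sorted = t_all[order]
        flag_sorted = obs_flag[order]
        inv = np.empty(len(t_all), dtype=int)
        inv[order] = np.arange(len(t_all))
        pos_of_new = inv[len(t_obs):]
        xy = np.zeros((len(t_all), 2))
        R = np.zeros((len(t_all), 2, 2))
        xy[inv[:len(t_obs)]] = self.obs_xy_km
        R[inv[:len(t_obs)]] = self.obs_R_km2
        return t_sorted, flag_sorted, pos_of_new, xy, R

    def smooth_at(self, times):
        """Smoothed state mean and covariance at arbitrary times."""
        t_h, observed, idx, xy, R = self._merged_timeline(times)
        filt = kalman_filter(self.beta, self.sigma, t_h, xy, R, observed)
        ms, Ps = _rts_smooth(self.beta, self.sigma, filt)
        return ms[idx], Ps[idx]


def prefilter_locations(obs: pd.DataFrame, max_speed_mps: float = 5.5,
                        spike_angle_deg: float = 15.0,
                        spike_leg_km: float = 2.5,
                        min_leg_km: float = 1.0,
                        center: tuple[float, float] | None = None) -> pd.DataFrame:
    """Remove locations implying unrealistic speeds or out-and-back spikes.

    Iteratively drops the location with the worst implied adjacent speed
    until all segment speeds are at or below ``max_speed_mps``, then removes
    spike points whose turn angle is below ``spike_angle_deg`` with both legs
    longer than ``spike_leg_km``.  Segments shorter than ``min_leg_km`` never
    trigger the speed rule: a pair of noisy fixes seconds apart implies an
    arbitrarily large speed without being evidence of a bad location.
    Idempotent: a clean table passes through unchanged.
    """
    df = obs.sort_values("time").reset_index(drop=True)
    if center is None:
        center = (float(df["lon"].median()), float(df["lat"].median()))
    x, y = geo_to_plane(df["lon"].to_numpy(), df["lat"].to_numpy(), *center)
    t = np.asarray(pd.DatetimeIndex(df["time"]).view("int64"), dtype=float) / 1e9
    keep = np.ones(len(df), dtype=bool)

    def speeds(idx):
        xx, yy, tt = x[idx], y[idx], t[idx]
        d = np.hypot(np.diff(xx), np.diff(yy))
        dt = np.maximum(np.diff(tt), 1.0)
        v = d * 1000.0 / dt
        v[d < min_leg_km] = 0.0
        return v

    while True:
        idx = np.flatnonzero(keep)
        if len(idx) < 3:
            raise ValueError("fewer than 3 locations remain after filtering")
        v = speeds(idx)
        if (v <= max_speed_mps).all():
            break
        # Score each interior point by the sum of its adjacent segment speeds.
        score = np.zeros(len(idx))
        score[:-1] += v
        score[1:] += v
        score[0] = v[0]
        score[-1] = v[-1]
        worst = int(np.argmax(score))
        keep[idx[worst]] = False

    # Spike removal: small turn angle with long legs on both sides.
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(keep)
        if len(idx) < 3:
            break
        xx, yy = x[idx], y[idx]
        v1 = np.stack([xx[1:-1] - xx[:-2], yy[1:-1] - yy[:-2]], axis=1)
        v2 = np.stack([xx[2:] - xx[1:-1], yy[2:] - yy[1:-1]], axis=1)
        l1 = np.linalg.norm(v1, axis=1)
        l2 = np.linalg.norm(v2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", v1, -v2) / np.maximum(l1 * l2, 1e-12)
        angle = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
        bad = (angle < spike_angle_deg) & (l1 > spike_leg_km) & (l2 > spike_leg_km)
        if bad.any():
            keep[idx[1 + int(np.flatnonzero(bad)[0])]] = False
            changed = True
    return df[keep].reset_index(drop=True)


def _prepare_obs(obs: pd.DataFrame, center=None):
    df = obs.sort_values("time").reset_index(drop=True)
    if center is None:
        center = (float(df["lon"].median()), float(df["lat"].median()))
    x, y = geo_to_plane(df["lon"].to_numpy(), df["lat"].to_numpy(), *center)
    sm = df.get("semi_major_m")
    if sm is None:
        sm = pd.Series(GPS_ELLIPSE95_M, index=df.index)
    sm = sm.fillna(GPS_ELLIPSE95_M)
    sb = df.get("semi_minor_m", sm).fillna(GPS_ELLIPSE95_M)
    ori = df.get("orientation_deg", pd.Series(0.0, index=df.index)).fillna(0.0)
    R = ellipse_to_cov_m2(sm.to_numpy(), sb.to_numpy(), ori.to_numpy()) / 1e6
    return df, center, np.stack([x, y], axis=1), R


def fit_ctcrw(obs: pd.DataFrame, center=None, error_inflation: float = 1.0,
              n_restarts: int = 3) -> CTCRWFit:
    """Maximum-likelihood CTCRW fit to a filtered location table.

    Requires at least 20 locations spanning at least one day.  Optimizes the
    Kalman-filter likelihood over (log beta, log sigma) with dispersed
    restarts; observation covariances come from each record's error ellipse
    (scaled by ``error_inflation`` if given).
    """
    df, center, xy, R = _prepare_obs(obs, center)
    if len(df) < 20:
        raise ValueError("need at least 20 locations to fit a CTCRW")
    times = pd.DatetimeIndex(df["time"])
    span_d = (times[-1] - times[0]).total_seconds() / 86400.0
    if span_d < 1.0:
        raise ValueError("locations must span at least one day")
    t_h = (times - times[0]).total_seconds().to_numpy() / 3600.0
    R = R * error_inflation

    def nll(theta):
        beta, sigma = np.exp(theta)
        if not (1e-4 < beta < 1e3 and 1e-4 < sigma < 1e3):
            return 1e12
        try:
            return -kalman_filter(beta, sigma, t_h, xy, R)["loglik"]
        except np.linalg.LinAlgError:
            return 1e12

    starts = [(0.0, 1.0), (-1.5, 0.0), (1.0, 2.0)][:n_restarts]
    best = None
    for s in starts:
        res = minimize(nll, np.asarray(s), method="Nelder-Mead",
                       options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"CTCRW optimization failed: {best}")
    beta, sigma = np.exp(best.x)
    return CTCRWFit(float(beta), float(sigma), error_inflation,
                    float(-best.fun), center, times, xy, R)


def predict_positions(fit: CTCRWFit, times, max_extrapolation_h: float = 6.0) -> pd.DataFrame:
    """Smoothed positions with uncertainty at the requested times.

    Returns a table with lon/lat, the 2x2 position covariance (m^2), and the
    95% error-ellipse semi-major axis sqrt(5.991 * lambda_max) in meters.
    Times beyond the deployment span plus ``max_extrapolation_h`` are flagged
    ``extrapolated``.
    """
    times = pd.DatetimeIndex(times)
    ms, Ps = fit.smooth_at(times)
    x, y = ms[:, 0], ms[:, 2]
    lon, lat = plane_to_geo(x, y, *fit.center)
    cov_m2 = Ps[:, [0, 0, 2, 2], [0, 2, 0, 2]].reshape(-1, 2, 2) * 1e6
    eig = np.clip(np.linalg.eigvalsh(cov_m2), 0.0, None)
    semi_major95 = np.sqrt(CHI2_95_2D * eig[:, -1])
    lo = fit.obs_time[0] - pd.Timedelta(hours=max_extrapolation_h)
    hi = fit.obs_time[-1] + pd.Timedelta(hours=max_extrapolation_h)
    extrapolated = (times < lo) | (times > hi)
    return pd.DataFrame({
        "time": times, "lon": lon, "lat": lat,
        "x_km": x, "y_km": y,
        "var_xx_m2": cov_m2[:, 0, 0], "var_xy_m2": cov_m2[:, 0, 1],
        "var_yy_m2": cov_m2[:, 1, 1],
        "ellipse95_semi_major_m": semi_major95,
        "extrapolated": extrapolated,
    })


@dataclass
class ImputationSet:
    """K posterior draws of the path, evaluated on a shared time grid."""

    times: pd.DatetimeIndex
    lon: np.ndarray      # (K, n_times)
    lat: np.ndarray
    x_km: np.ndarray
    y_km: np.ndarray
    seed: int

    @property
    def K(self) -> int:
        return self.lon.shape[0]


def impute_tracks(fit: CTCRWFit, times, K: int = 20, seed: int = 0) -> ImputationSet:
    """Draw K independent paths from the joint smoothing posterior.

    Forward-filter backward-sampling on the union of observation and request
    times: the terminal state is drawn from its filtered distribution and
    earlier states from the exact Gaussian conditional given the following
    sampled state.  Across-imputation means and variances converge to the
    smoother's as K grows.
    """
    if K < 2:
        raise ValueError("need at least K=2 imputations")
    times = pd.DatetimeIndex(times)
    t_h, observed, idx, xy, R = fit._merged_timeline(times)
    filt = kalman_filter(fit.beta, fit.sigma, t_h, xy, R, observed)
    mf, Pf, mp, Pp = filt["mf"], filt["Pf"], filt["mp"], filt["Pp"]
    n = len(t_h)
    rng = np.random.default_rng(seed)

    def _sample(mean, cov, size=None):
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
        z = rng.standard_normal((4,) if size is None else (size, 4))
        return mean + z @ L.T

    draws = np.empty((K, n, 4))
    draws[:, -1, :] = _sample(mf[-1], Pf[-1], size=K)
    for i in range(n - 2, -1, -1):
        dt = t_h[i + 1] - t_h[i]
        A, _ = _transition4(fit.beta, fit.sigma, max(dt, 1e-9))
        J = Pf[i] @ A.T @ np.linalg.inv(Pp[i + 1])
        cond_cov = Pf[i] - J @ Pp[i + 1] @ J.T
        w, V = np.linalg.eigh((cond_cov + cond_cov.T) / 2.0)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        mean = mf[i] + (draws[:, i + 1, :] - mp[i + 1]) @ J.T
        draws[:, i, :] = mean + rng.standard_normal((K, 4)) @ L.T

    x = draws[:, idx, 0]
    y = draws[:, idx, 2]
    lon, lat = plane_to_geo(x, y, *fit.center)
    return ImputationSet(times, lon, lat, x, y, int(seed))


def reroute_land(points: pd.DataFrame, bathy, isobath_m: float = 20.0,
                 max_search_km: float = 200.0) -> pd.DataFrame:
    """Move on-land or too-shallow points to the nearest sufficiently deep cell.

    Any point whose seafloor depth is shallower than ``isobath_m`` is
    relocated to the nearest grid cell with depth >= isobath, and the moved
    distance is recorded in ``rerouted_km``.
    """
    import xarray as xr

    lons = bathy["lon"].to_numpy()
    lats = bathy["lat"].to_numpy()
    center = (float(np.mean(lons)), float(np.mean(lats)))
    glon, glat = np.meshgrid(lons, lats)
    deep = bathy.to_numpy() >= isobath_m
    if not deep.any():
        raise ValueError("no cells at or beyond the isobath")
    gx, gy = geo_to_plane(glon[deep], glat[deep], *center)
    tree = cKDTree(np.stack([gx, gy], axis=1))
    deep_lon = glon[deep]
    deep_lat = glat[deep]

    out = points.copy().reset_index(drop=True)
    px, py = geo_to_plane(out["lon"].to_numpy(), out["lat"].to_numpy(), *center)
    depth_at = bathy.sel(
        lon=xr.DataArray(out["lon"].to_numpy(), dims="pt"),
        lat=xr.DataArray(out["lat"].to_numpy(), dims="pt"),
        method="nearest").to_numpy()
    shallow = depth_at < isobath_m
    out["rerouted_km"] = 0.0
    if shallow.any():
        d, j = tree.query(np.stack([px[shallow], py[shallow]], axis=1))
        if np.any(d > max_search_km):
            raise ValueError("no sea cell within the search radius for some points")
        out.loc[shallow, "lon"] = deep_lon[j]
        out.loc[shallow, "lat"] = deep_lat[j]
        out.loc[shallow, "rerouted_km"] = d
    return out
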