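"""Environmental covariates at dive locations and the predictor screening rules.

Rasters are xarray objects (``lat``/``lon`` coordinate vectors, optional
``time`` dimension for daily fields).  Extraction is nearest-cell: dive
positions already carry kilometer-scale uncertainty, so sub-cell
interpolation adds nothing.  Daily fields are matched on the dive's local
(HST) calendar date; a 30-day-lagged chlorophyll value is taken from the
layer dated exactly 30 days earlier.  Before modeling, pairwise Pearson
correlations among candidate predictors are screened: within any pair with
|r| above the threshold (default 0.5), only the higher-priority predictor is
retained.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .diel import HST_OFFSET_HOURS

#: Retention priority for the correlation screen (earlier wins).  Lagged
#: chlorophyll outranks the contemporaneous product and SST.
DEFAULT_PRIORITY = [
    "time_of_day", "moon_phase", "slope", "current_magnitude",
    "chl_log10_lag30", "mld", "chl_log10", "sst", "seafloor_depth",
]


def slope_from_bathymetry(bathy: xr.DataArray) -> xr.DataArray:
    """Seafloor slope in degrees from a depth raster (Horn 3x3 gradient).

    Cell sizes are scaled to meters on a sphere (the east-west size shrinks
    with cos(latitude)).  The result is in [0, 90) and is invariant to adding
    a constant to the depths.
    """
    if bathy.shape[0] < 3 or bathy.shape[1] < 3:
        raise ValueError("bathymetry grid must be at least 3x3")
    z = bathy.transpose("lat", "lon").to_numpy().astype(float)
    lats = bathy["lat"].to_numpy()
    lons = bathy["lon"].to_numpy()
    dlat = float(np.mean(np.diff(lats)))
    dlon = float(np.mean(np.diff(lons)))
    m_per_deg = 111_194.9  # spherical degree of latitude
    dy = dlat * m_per_deg
    dx = dlon * m_per_deg * np.cos(np.deg2rad(lats))[:, None]

    zp = np.pad(z, 1, mode="edge")
    # Horn's weights on the 3x3 neighborhood.
    gx = ((zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
          - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])) / (8.0 * dx)
    gy = ((zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
          - (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])) / (8.0 * dy)
    slope = np.rad2deg(np.arctan(np.hypot(gx, gy)))
    return xr.DataArray(slope, coords=bathy.coords, dims=("lat", "lon"),
                        name="slope", attrs={"units": "degrees"})


def derive_fields(env: xr.Dataset) -> xr.Dataset:
    """Add current magnitude and log10 chlorophyll layers to an env stack.

    ``current_magnitude`` = sqrt(u^2 + v^2) cellwise; ``chl_log10`` is
    log10(chl) with non-positive chlorophyll mapped to NaN (nodata), never
    -inf.
    """
    for a, b in (("u", "v"), ("u", "chl")):
        if env[a].shape != env[b].shape:
            raise ValueError(f"grid mismatch between layers {a!r} and {b!r}")
    out = env.copy()
    out["current_magnitude"] = np.hypot(env["u"], env["v"])
    out["current_magnitude"].attrs["units"] = "m s-1"
    chl = env["chl"].where(env["chl"] > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["chl_log10"] = np.log10(chl)
    return out


def extract_at(raster, lon, lat, time=None, lag_days: int = 0):
    """Nearest-cell raster lookup at points, with daily-layer date matching.

    For time-varying rasters the layer is chosen by the point's HST calendar
    date minus ``lag_days``.  Out-of-bounds points return NaN.  Returns a
    numpy array aligned with the input points.
    """
    lon = np.atleast_1d(np.asarray(lon, float))
    lat = np.atleast_1d(np.asarray(lat, float))
    lon_ax = raster["lon"].to_numpy()
    lat_ax = raster["lat"].to_numpy()
    half_lon = abs(float(np.mean(np.diff(lon_ax)))) / 2 if len(lon_ax) > 1 else np.inf
    half_lat = abs(float(np.mean(np.diff(lat_ax)))) / 2 if len(lat_ax) > 1 else np.inf
    oob = (
        (lon < lon_ax.min() - half_lon) | (lon > lon_ax.max() + half_lon)
        | (lat < lat_ax.min() - half_lat) | (lat > lat_ax.max() + half_lat)
    )

    if "time" in raster.dims:
        if time is None:
            raise ValueError("time-varying raster requires point times")
        t = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(time)))
        dates = (t + pd.Timedelta(hours=HST_OFFSET_HOURS)).normalize() \
            - pd.Timedelta(days=lag_days)
        out = np.full(len(lon), np.nan)
        for d in dates.unique():
            m = np.asarray(dates == d)
            layer = raster.sel(time=d, method="nearest")
            out[m] = layer.sel(
                lon=xr.DataArray(lon[m], dims="pt"),
                lat=xr.DataArray(lat[m], dims="pt"),
                method="nearest").to_numpy()
    else:
        out = raster.sel(
            lon=xr.DataArray(lon, dims="pt"),
            lat=xr.DataArray(lat, dims="pt"),
            method="nearest").to_numpy().astype(float)
    out[oob] = np.nan
    return out


def dive_covariates(dives: pd.DataFrame, bathy: xr.DataArray,
                    env: xr.Dataset, slope: xr.DataArray | None = None) -> pd.DataFrame:
    """Assemble the modeling covariate table for located dives.

    ``dives`` needs columns ``start``, ``lon``, ``lat``.  Adds time-of-day
    (fractional HST hours), moon phase, seafloor depth and slope, current
    magnitude, mixed layer depth, SST, contemporaneous and 30-day-lagged
    log10 chlorophyll, and the chlorophyll land flag.
    """
    from .diel import local_hour, moon_phase

    env = derive_fields(env) if "current_magnitude" not in env else env
    if slope is None:
        slope = slope_from_bathymetry(bathy)
    out = dives.copy().reset_index(drop=True)
    t = pd.DatetimeIndex(out["start"])
    lon = out["lon"].to_numpy()
    lat = out["lat"].to_numpy()
    out["time_of_day"] = local_hour(t)
    out["moon_phase"] = moon_phase(t)
    out["seafloor_depth"] = extract_at(bathy, lon, lat)
    out["slope"] = extract_at(slope, lon, lat)
    out["current_magnitude"] = extract_at(env["current_magnitude"], lon, lat, t)
    out["mld"] = extract_at(env["mld"], lon, lat, t)
    out["sst"] = extract_at(env["sst"], lon, lat, t)
    out["chl_log10"] = extract_at(env["chl_log10"], lon, lat, t)
    out["chl_log10_lag30"] = extract_at(env["chl_log10"], lon, lat, t, lag_days=30)
    flag = extract_at(env["chl_flag"], lon, lat, t)
    out["chl_flagged"] = np.nan_to_num(flag, nan=1.0) > 0.5
    return out


def correlation_screen(table: pd.DataFrame, candidates: list[str] | None = None,
                       threshold: float = 0.5,
                       priority: list[str] | None = None):
    """Drop the lower-priority member of each highly correlated predictor pair.

    Pearson correlations are computed on complete cases; pairs with
    |r| > ``threshold`` lose their lower-priority member.  Zero-variance
    columns are excluded with a warning.  Returns
    ``(retained_names, correlation_matrix)``.
    """
    priority = priority or DEFAULT_PRIORITY
    if candidates is None:
        candidates = [c for c in priority if c in table.columns]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate covariates")
    sub = table[candidates].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    usable = []
    for c in candidates:
        if sub[c].std() == 0:
            warnings.warn(f"covariate {c!r} has zero variance; excluded")
        else:
            usable.append(c)
    corr = sub[usable].corr(method="pearson")

    def rank(name: str) -> int:
        return priority.index(name) if name in priority else len(priority)

    retained = sorted(usable, key=rank)
    dropped: set[str] = set()
    for i, a in enumerate(retained):
        if a in dropped:
            continue
        for b in retained[i + 1:]:
            if b in dropped:
                continue
            if abs(corr.loc[a, b]) > threshold:
                dropped.add(b)
    kept = [c for c in retained if c not in dropped]
    return kept, corr
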