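"""Probable near-seafloor dive classification from imputed positions.

A dive that appears to reach the seafloor may be an artifact of location
uncertainty: if plausible positions for the dive spread across very different
seafloor depths, the apparent dive-to-seafloor match is uninformative.  The
classification therefore extracts seafloor depth beneath each of K imputed
positions per dive (default K = 20) and keeps a dive as a probable
near-seafloor dive only when

* the sample standard deviation of the K seafloor depths is at most
  ``sd_max`` (default 100 m, a spatial-precision filter), and
* |max seafloor depth - dive depth| is at most ``diff_max`` (default 100 m,
  so the dive bottoms out within 100 m of the deepest plausible seafloor).

Candidate dives are those already screened to a 95% position-ellipse
semi-major axis of 4 km or less.  The dive-depth to seafloor-depth ratio is
computed at the smoothed point-estimate position (values near 1 indicate
dives using the full water column).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .covariates import extract_at
from .track import ImputationSet

SD_MAX_M = 100.0
DIFF_MAX_M = 100.0
MAX_NODATA_FRACTION = 0.25


def compute_seafloor_stats(dives: pd.DataFrame, imputations: ImputationSet,
                           bathy: xr.DataArray,
                           max_nodata_fraction: float = MAX_NODATA_FRACTION) -> pd.DataFrame:
    """Per-dive seafloor-depth statistics across imputed positions.

    ``dives`` must carry ``start`` times present in the imputation grid,
    plus ``depth`` and point-estimate ``lon``/``lat``.  Returns one row per
    dive with the K seafloor depths' sample SD and maximum, the depth
    difference (max seafloor - dive depth), and the dive/seafloor ratio at
    the point estimate.  Dives whose imputed positions fall outside the
    bathymetry more than ``max_nodata_fraction`` of the time are dropped
    with a warning.
    """
    times = pd.DatetimeIndex(dives["start"])
    grid = imputations.times
    pos = grid.get_indexer(times)
    if (pos < 0).any():
        raise ValueError("imputation grid does not cover all dive times")

    K = imputations.K
    sf = np.empty((K, len(dives)))
    for k in range(K):
        sf[k] = extract_at(bathy, imputations.lon[k, pos], imputations.lat[k, pos])

    n_nodata = np.isnan(sf).sum(axis=0)
    ok = n_nodata <= max_nodata_fraction * K
    if (~ok).any():
        warnings.warn(f"dropped {(~ok).sum()} dives with >25% imputations off-raster")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(sf, axis=0, ddof=1)
        mx = np.nanmax(sf, axis=0)
    point_sf = extract_at(bathy, dives["lon"].to_numpy(), dives["lat"].to_numpy())
    depth = dives["depth"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):  # land: ratio undefined
        ratio = np.where(point_sf > 0, depth / point_sf, np.nan)
    out = pd.DataFrame({
        "animal_id": dives["animal_id"].to_numpy(),
        "start": times,
        "depth": depth,
        "n_imputations": K - n_nodata,
        "sd_seafloor": sd,
        "max_seafloor": mx,
        "depth_difference": mx - depth,
        "point_seafloor": point_sf,
        "ratio": ratio,
    })
    return out[ok].reset_index(drop=True)


def classify_near_seafloor(stats: pd.DataFrame, sd_max: float = SD_MAX_M,
                           diff_max: float = DIFF_MAX_M) -> pd.Series:
    """Boolean per dive: probable near-seafloor under the two-filter chain."""
    return (stats["sd_seafloor"] <= sd_max) & (stats["depth_difference"].abs() <= diff_max)


def summarize_near_seafloor(stats: pd.DataFrame, probable: pd.Series,
                            diel_category: pd.Series | None = None,
                            shape: pd.Series | None = None) -> pd.DataFrame:
    """Per-animal summary of candidate and probable near-seafloor dives.

    For each animal: candidate count, probable count and percentage, median
    and range of probable dive depth, median and minimum depth/seafloor
    ratio, and (if provided) shape and diel-category counts.  Range entries
    are omitted (NaN) for animals with a single probable dive.
    """
    df = stats.copy()
    df["probable"] = probable.to_numpy()
    if diel_category is not None:
        df["diel"] = diel_category.to_numpy()
    if shape is not None:
        df["shape"] = shape.to_numpy()
    rows = []
    for animal, sub in df.groupby("animal_id", sort=True):
        prob = sub[sub["probable"]]
        n_cand, n_prob = len(sub), len(prob)
        row = {
            "animal_id": animal,
            "n_candidates": n_cand,
            "n_probable": n_prob,
            "pct_probable": 100.0 * n_prob / n_cand if n_cand else np.nan,
            "median_depth": prob["depth"].median() if n_prob else np.nan,
            "depth_min": prob["depth"].min() if n_prob > 1 else np.nan,
            "depth_max": prob["depth"].max() if n_prob > 1 else np.nan,
            "median_ratio": prob["ratio"].median() if n_prob else np.nan,
            "min_ratio": prob["ratio"].min() if n_prob > 1 else np.nan,
        }
        if diel_category is not None:
            for cat in ("dawn", "day", "dusk", "night"):
                row[f"n_{cat}"] = int((prob["diel"] == cat).sum())
        if shape is not None:
            for s in ("square", "u", "v"):
                row[f"n_{s}"] = int((prob["shape"] == s).sum())
        if n_cand == 0:
            row["flag"] = "no_candidates"
        rows.append(row)
    return pd.DataFrame(rows)


def hex_grid_summary(dives: pd.DataFrame, cell_area_km2: float = 750.0) -> pd.DataFrame:
    """Dive count, mean/max depth, and depth CV on a hexagonal spatial grid.

    Cells are pointy-top hexagons of the requested area on the local planar
    projection; cells with a single dive are excluded.
    """
    from .projection import geo_to_plane

    center = (float(dives["lon"].median()), float(dives["lat"].median()))
    x, y = geo_to_plane(dives["lon"].to_numpy(), dives["lat"].to_numpy(), *center)
    # Hexagon with area A has circumradius R = sqrt(2 A / (3 sqrt(3))).
    R = np.sqrt(2.0 * cell_area_km2 / (3.0 * np.sqrt(3.0)))
    # Axial rounding on a hex lattice.
    q = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / R
    r = (2.0 / 3.0 * y) / R
    def _round_axial(q, r):
        s = -q - r
        rq, rr, rs = np.round(q), np.round(r), np.round(s)
        dq, dr, ds = np.abs(rq - q), np.abs(rr - r), np.abs(rs - s)
        fix_q = (dq > dr) & (dq > ds)
        fix_r = ~fix_q & (dr > ds)
        rq[fix_q] = -rr[fix_q] - rs[fix_q]
        rr[fix_r] = -rq[fix_r] - rs[fix_r]
        return rq.astype(int), rr.astype(int)
    qi, ri = _round_axial(q, r)
    df = dives.copy()
    df["cell"] = list(zip(qi, ri))
    g = df.groupby("cell")["depth"].agg(["count", "mean", "max", "std"])
    g = g[g["count"] > 1]
    g["cv_percent"] = 100.0 * g["std"] / g["mean"]
    return g.rename(columns={"count": "n_dives", "mean": "mean_depth",
                             "max": "max_depth"}).reset_index()
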