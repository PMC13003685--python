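"""Dive rates, hour-unit construction, and median-of-individuals summaries.

Dive rate is the number of standardized dives divided by the summed duration
of dive and surface records (not wall-clock time), so transmission gaps never
enter the denominator.  For diel-specific rates, surface records are first
split at diel-category boundaries so each category's denominator contains
exactly the time spent in it.  Hourly modeling units are animal x date x
HST-hour cells with the dive count and covered time; cells with less than
75% coverage are dropped before modeling.  Group summaries follow the
median-of-individuals convention: a median (or proportion) per animal first,
then the grand mean, SD, and CV across animals — never pooled dives.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diel import HST_OFFSET_HOURS, diel_category, moon_phase, split_interval

COVERAGE_MIN = 0.75


def annotate_diel(records: pd.DataFrame, position_lookup) -> pd.DataFrame:
    """Label each record with the diel category of its start time.

    ``position_lookup(animal_id, times) -> (lon, lat)`` supplies positions
    (e.g., CTCRW-predicted positions, or a fixed deployment locality for
    data without geolocation).  Dives are labeled by start time; use
    :func:`split_records_diel` to split long surface records by category.
    """
    out = records.copy().reset_index(drop=True)
    cats = np.empty(len(out), dtype=object)
    for animal, sub in out.groupby("animal_id", sort=False):
        lon, lat = position_lookup(animal, pd.DatetimeIndex(sub["start"]))
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        for j, (i, row) in enumerate(sub.iterrows()):
            cats[i] = diel_category(row["start"], lon[j], lat[j])
    out["diel"] = cats
    return out


def split_records(records: pd.DataFrame, mode: str, position_lookup=None) -> pd.DataFrame:
    """Split surface records at diel or HST clock-hour boundaries.

    Dive records are never split: a dive belongs to the category/hour of its
    start.  Sub-records inherit all parent fields; durations are the exact
    sub-interval lengths, so total covered time is conserved.  Adds a
    ``diel`` or ``hour`` label column.
    """
    label_col = "diel" if mode == "diel" else "hour"
    rows = []
    for _, row in records.reset_index(drop=True).iterrows():
        if mode == "diel":
            if position_lookup is None:
                raise ValueError("diel splitting requires a position lookup")
            lon, lat = position_lookup(row["animal_id"], pd.DatetimeIndex([row["start"]]))
            lon, lat = float(np.atleast_1d(lon)[0]), float(np.atleast_1d(lat)[0])
        if row["kind"] == "dive":
            d = row.to_dict()
            if mode == "diel":
                d[label_col] = diel_category(row["start"], lon, lat)
            else:
                d[label_col] = f"{int((row['start'].hour - 10) % 24):02d}"
            rows.append(d)
            continue
        pieces = split_interval(row["start"], row["end"], mode,
                                lon=lon if mode == "diel" else None,
                                lat=lat if mode == "diel" else None)
        # Distribute the recorded duration over pieces in proportion to
        # span, so summed child durations equal the parent duration exactly.
        span = (row["end"] - row["start"]).total_seconds()
        for p in pieces:
            d = row.to_dict()
            d["start"], d["end"] = p.start, p.end
            d["duration"] = row["duration"] * (p.duration_s / span)
            d[label_col] = p.label
            rows.append(d)
    return pd.DataFrame(rows).reset_index(drop=True)


def dive_rate(records: pd.DataFrame, grouping: str = "overall") -> pd.DataFrame:
    """Dives per hour per animal, overall or per diel category.

    ``grouping='diel_category'`` requires records already labeled (and
    surface records pre-split) with a ``diel`` column.  The denominator is
    the summed duration of all records in the group; a group with zero
    covered time yields an undefined (NaN) rate with a flag, never 0.
    """
    if grouping == "overall":
        keys = ["animal_id"]
    elif grouping == "diel_category":
        if "diel" not in records.columns:
            raise ValueError("diel grouping requires a 'diel' column (see split_records)")
        keys = ["animal_id", "diel"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for key, sub in records.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        hours = sub["duration"].sum() / 3600.0
        n_dives = int((sub["kind"] == "dive").sum())
        rows.append(dict(zip(keys, key)) | {
            "n_dives": n_dives,
            "covered_hours": hours,
            "rate_per_h": n_dives / hours if hours > 0 else np.nan,
            "undefined": hours <= 0,
        })
    return pd.DataFrame(rows)


def build_hour_units(records: pd.DataFrame, coverage_min: float = COVERAGE_MIN,
                     keep_dropped: bool = False) -> pd.DataFrame:
    """Animal x HST-date x hour modeling units for the hourly dive-rate model.

    ``records`` must be pre-split by clock hour (``hour`` column).  Each unit
    counts the dives starting in that hour and the covered fraction of the
    hour; units under ``coverage_min`` are dropped (or flagged when
    ``keep_dropped``).  Moon phase is evaluated at the unit's midpoint.
    """
    if "hour" not in records.columns:
        raise ValueError("records must be split by clock hour first")
    df = records.copy()
    local_start = pd.DatetimeIndex(df["start"]) + pd.Timedelta(hours=HST_OFFSET_HOURS)
    df["date"] = local_start.normalize()
    rows = []
    for (animal, date, hour), sub in df.groupby(["animal_id", "date", "hour"], sort=True):
        covered_h = sub["duration"].sum() / 3600.0
        mid_utc = (pd.Timestamp(date) + pd.Timedelta(hours=int(hour) + 0.5)
                   - pd.Timedelta(hours=HST_OFFSET_HOURS))
        rows.append({
            "animal_id": animal, "date": date, "hour": int(hour),
            "n_dives": int((sub["kind"] == "dive").sum()),
            "covered_hours": min(covered_h, 1.0),
            "moon_phase": moon_phase(mid_utc),
            "retained": covered_h >= coverage_min,
        })
    units = pd.DataFrame(rows)
    if not keep_dropped:
        units = units[units["retained"]].reset_index(drop=True)
    return units


def depth_bin_label(depth_m: float, bin_width: float = 100.0) -> int:
    """Upper edge of the depth bin containing a dive (75 m -> 100; 150 -> 200)."""
    return int(np.ceil(depth_m / bin_width) * bin_width)


def group_summary(per_dive: pd.DataFrame, metric: str,
                  grouping: str | None = None) -> pd.DataFrame:
    """Grand mean of per-animal medians (or proportions), with SD and CV.

    ``metric``: a numeric column name (summarized by per-animal median) or
    ``"shape_proportions"`` (per-animal proportions of square/u/v dives).
    ``grouping``: optional column to summarize within (e.g., ``diel``,
    ``population``).  Single-animal groups report SD/CV as NaN, not 0.
    """
    keys = [grouping] if grouping else []

    if metric == "shape_proportions":
        per_animal = (
            per_dive.groupby(keys + ["animal_id"])["shape"]
            .value_counts(normalize=True).rename("value").reset_index()
        )
        out_rows = []
        for key, sub in per_animal.groupby(keys + ["shape"], sort=True):
            key = key if isinstance(key, tuple) else (key,)
            vals = sub["value"]
            out_rows.append(dict(zip(keys + ["shape"], key)) | _grand(vals))
        return pd.DataFrame(out_rows)

    per_animal = per_dive.groupby(keys + ["animal_id"])[metric].median().rename("value").reset_index()
    if not keys:
        return pd.DataFrame([_grand(per_animal["value"])])
    rows = []
    for key, sub in per_animal.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(keys, key)) | _grand(sub["value"]))
    return pd.DataFrame(rows)


def _grand(values: pd.Series) -> dict:
    n = len(values)
    gm = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else np.nan
    return {
        "grand_mean": gm,
        "sd": sd,
        "cv_percent": 100.0 * sd / gm if n > 1 and gm != 0 else np.nan,
        "n_individuals": n,
    }


def interdive_surface_durations(records: pd.DataFrame,
                                max_gap_tolerance_s: float = 600.0) -> pd.DataFrame:
    """Surface time between consecutive dives, per animal.

    Only intervals with no data gap longer than the tolerance between the
    two dives are kept (others are censored, since the true surface duration
    is unknown across a transmission gap).
    """
    rows = []
    for animal, sub in records.groupby("animal_id", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        dive_idx = np.flatnonzero((sub["kind"] == "dive").to_numpy())
        for a, b in zip(dive_idx[:-1], dive_idx[1:]):
            between = sub.iloc[a + 1:b]
            span = (sub.loc[b, "start"] - sub.loc[a, "end"]).total_seconds()
            covered = between["duration"].sum()
            if span - covered <= max_gap_tolerance_s:
                rows.append({"animal_id": animal, "surface_s": covered,
                             "start": sub.loc[a, "end"]})
    return pd.DataFrame(rows)
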