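"""Solar/lunar geometry, civil diel categories, and interval splitting.

Diel categories follow the civil-twilight convention used in diel analyses of
marine predator behavior: the sun more than 6 degrees above the horizon is
``day``, more than 6 degrees below is ``night``, and the transition band
[-6, +6] degrees is ``dawn`` when the sun is rising and ``dusk`` when it is
setting.  Solar elevation is computed from standard low-precision solar
ephemeris formulas (geometric elevation, no refraction) with an accuracy
contract of +/-0.5 degrees, which is ample for a 12-degree-wide band.

Local clock time is Hawaiian Standard Time, fixed at UTC-10 with no daylight
saving; it is applied only when a clock hour or time-of-day covariate is
needed.  All stored timestamps are UTC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HST_OFFSET_HOURS = -10.0

#: Mean synodic month, days.
SYNODIC_MONTH_DAYS = 29.530588853

#: A reference new moon: 2000-01-06 18:14 UTC.
_NEW_MOON_EPOCH = pd.Timestamp("2000-01-06 18:14:00")

_DIEL_BAND_DEG = 6.0

DIEL_CATEGORIES = ("dawn", "day", "dusk", "night")


def _julian_century(time: np.ndarray) -> np.ndarray:
    """Julian centuries since J2000.0 for datetime64[ns] values."""
    j2000 = np.datetime64("2000-01-01T12:00:00")
    days = (time - j2000) / np.timedelta64(1, "D")
    return days / 36525.0


def solar_elevation(time, lon, lat):
    """Geometric solar elevation in degrees.

    Parameters
    ----------
    time : datetime-like or array of datetime64
        Instant(s) in UTC.
    lon, lat : float or array
        Longitude (east positive) and latitude in degrees.

    Returns
    -------
    float or ndarray
        Elevation of the solar center above the horizon, degrees.  No
        atmospheric refraction is applied.
    """
    t = np.asarray(pd.to_datetime(time).to_numpy() if not isinstance(time, np.ndarray) else time)
    scalar = t.ndim == 0
    t = np.atleast_1d(t).astype("datetime64[ns]")
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))

    T = _julian_century(t)
    # Geometric mean longitude and anomaly of the sun (degrees).
    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.deg2rad(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.deg2rad(omega))

    # Obliquity of the ecliptic, corrected.
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(np.deg2rad(omega))
    eps_r = np.deg2rad(eps)

    decl = np.arcsin(np.sin(eps_r) * np.sin(np.deg2rad(app_long)))

    # Equation of time, minutes.
    y = np.tan(eps_r / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )

    day_start = t.astype("datetime64[D]").astype("datetime64[ns]")
    minutes_utc = (t - day_start) / np.timedelta64(1, "m")
    true_solar_min = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)
    hour_angle = true_solar_min / 4.0 - 180.0

    lat_r = np.deg2rad(lat)
    elev = np.arcsin(
        np.sin(lat_r) * np.sin(decl)
        + np.cos(lat_r) * np.cos(decl) * np.cos(np.deg2rad(hour_angle))
    )
    out = np.rad2deg(elev)
    return float(out[0]) if scalar and out.size == 1 else out


def moon_phase(time) -> float | np.ndarray:
    """Mean lunar phase angle in radians, [0, 2*pi).

    0 is new moon, pi is full moon.  Computed as the mean synodic phase
    elapsed since a reference new moon; monotone within each synodic month.
    """
    t = pd.to_datetime(time)
    if isinstance(t, pd.Timestamp):
        days = (t - _NEW_MOON_EPOCH).total_seconds() / 86400.0
        return float(np.mod(days / SYNODIC_MONTH_DAYS, 1.0) * 2.0 * np.pi)
    days = (t - _NEW_MOON_EPOCH).total_seconds() / 86400.0
    return np.mod(np.asarray(days) / SYNODIC_MONTH_DAYS, 1.0) * 2.0 * np.pi


def local_hour(time, offset_hours: float = HST_OFFSET_HOURS):
    """Fractional local clock hour in [0, 24) for UTC input (HST default)."""
    t = pd.to_datetime(time)
    if isinstance(t, pd.Timestamp):
        h = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
        return float(np.mod(h + offset_hours, 24.0))
    h = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    return np.mod(np.asarray(h) + offset_hours, 24.0)


def _is_rising(time, lon, lat, half_window_min: float = 5.0) -> bool:
    t = pd.Timestamp(time)
    dt = pd.Timedelta(minutes=half_window_min)
    return solar_elevation(t + dt, lon, lat) > solar_elevation(t - dt, lon, lat)


def diel_category(time, lon, lat) -> str:
    """Civil diel category at an instant and position.

    ``day`` when the sun is above +6 deg, ``night`` below -6 deg; within the
    band, ``dawn`` if the sun is rising (elevation increasing over a +/-5 min
    window) and ``dusk`` otherwise.
    """
    elev = solar_elevation(pd.Timestamp(time), lon, lat)
    if elev > _DIEL_BAND_DEG:
        return "day"
    if elev < -_DIEL_BAND_DEG:
        return "night"
    return "dawn" if _is_rising(time, lon, lat) else "dusk"


@dataclass(frozen=True)
class SubInterval:
    start: pd.Timestamp
    end: pd.Timestamp
    label: str

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def _refine_boundary(t_lo, t_hi, lon, lat, left_label, tol_s: float = 0.001) -> pd.Timestamp:
    """Bisect for the instant the diel category changes from ``left_label``."""
    # Force nanosecond resolution: coarser-unit Timestamps truncate
    # sub-second arithmetic and stall the bisection.
    lo, hi = pd.Timestamp(t_lo).as_unit("ns"), pd.Timestamp(t_hi).as_unit("ns")
    while (hi - lo).total_seconds() > tol_s:
        mid = lo + (hi - lo) / 2
        if diel_category(mid, lon, lat) == left_label:
            lo = mid
        else:
            hi = mid
    return hi


def split_interval(start, end, mode: str, lon: float | None = None,
                   lat: float | None = None,
                   coarse_step_s: float | None = None) -> list[SubInterval]:
    """Partition [start, end) at diel-category or HST clock-hour boundaries.

    Returns contiguous sub-intervals that exactly tile the parent (child
    durations sum to the parent duration by construction), each labeled with
    its diel category or local clock hour ("00".."23").
    """
    start = pd.Timestamp(start).as_unit("ns")
    end = pd.Timestamp(end).as_unit("ns")
    if end <= start:
        raise ValueError("interval must have positive duration")

    if mode == "clock_hour":
        pieces: list[SubInterval] = []
        t = start
        while t < end:
            local = t + pd.Timedelta(hours=HST_OFFSET_HOURS)
            next_local = (local + pd.Timedelta(hours=1)).floor("h")
            boundary = next_local - pd.Timedelta(hours=HST_OFFSET_HOURS)
            seg_end = min(boundary, end)
            pieces.append(SubInterval(t, seg_end, f"{local.hour:02d}"))
            t = seg_end
        return pieces

    if mode != "diel":
        raise ValueError(f"unknown split mode {mode!r}")
    if lon is None or lat is None:
        raise ValueError("diel splitting requires lon and lat")

    # Coarse scan, then bisection on each detected category change.  The
    # shortest diel block (dawn/dusk, ~20+ min at low latitude) bounds the
    # scan step needed to catch every change.
    dur_s = (end - start).total_seconds()
    if coarse_step_s is None:
        coarse_step_s = float(np.clip(dur_s / 8.0, 30.0, 600.0))
    n = max(int(np.ceil(dur_s / coarse_step_s)), 1)
    grid = [start + (end - start) * (i / n) for i in range(n + 1)]
    labels = [diel_category(t, lon, lat) for t in grid]

    pieces = []
    seg_start = start
    cur = labels[0]
    for i in range(1, len(grid)):
        if labels[i] != cur:
            boundary = _refine_boundary(grid[i - 1], grid[i], lon, lat, cur)
            pieces.append(SubInterval(seg_start, boundary, cur))
            seg_start = boundary
            cur = labels[i]
    pieces.append(SubInterval(seg_start, end, cur))
    return pieces
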