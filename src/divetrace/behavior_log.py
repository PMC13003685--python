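"""Reading, quality control, and standardization of satellite-tag behavior logs.

Depth-transmitting satellite tags summarize vertical behavior as an
alternating sequence of "dive" and "surface" records, each with start/end
times, minimum/maximum estimates of depth and duration, and an onboard dive
shape code (square / u / v).  Because onboard dive-detection thresholds vary
across deployments, analyses standardize the log to a common definition: a
record is kept as a dive only if it is at least ``depth_threshold`` meters
deep (default 50 m) AND at least ``duration_threshold`` seconds long (default
120 s); everything else is treated as surface time, and runs of consecutive
surface records are merged.

Records are handled as pandas DataFrames with columns::

    animal_id, kind ("dive"|"surface"), start, end (UTC timestamps),
    depth_min, depth_max, dur_min, dur_max, shape, depth, duration

where ``depth`` and ``duration`` are the means of the reported min/max
brackets (the analysis values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "animal_id", "kind", "start", "end",
    "depth_min", "depth_max", "dur_min", "dur_max",
    "shape", "depth", "duration",
]

#: Default column mapping for Wildlife-Computers-style *-Behavior.csv files.
DEFAULT_DIALECT = {
    "kind": "What",
    "start": "Start",
    "end": "End",
    "dur_min": "DurationMin",
    "dur_max": "DurationMax",
    "depth_min": "DepthMin",
    "depth_max": "DepthMax",
    "shape": "Shape",
    "animal_id": "DeployID",
}

DEPTH_THRESHOLD_M = 50.0
DURATION_THRESHOLD_S = 120.0


def read_behavior_log(path, dialect: dict | None = None,
                      animal_id: str | None = None) -> pd.DataFrame:
    """Read a behavior-log CSV into a typed, sorted record table.

    Parameters
    ----------
    path : str or file-like
        CSV with at least record type, start/end timestamps, duration
        min/max, depth min/max and shape columns.
    dialect : dict, optional
        Mapping from canonical field names to CSV column names; defaults to
        the Wildlife Computers behavior-log layout.
    animal_id : str, optional
        Used when the file has no animal-id column.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path)

    required = ["kind", "start", "end", "dur_min", "dur_max", "depth_min", "depth_max"]
    for key in required:
        if dialect[key] not in raw.columns:
            raise ValueError(f"behavior log is missing required column {dialect[key]!r}")

    df = pd.DataFrame()
    df["animal_id"] = (
        raw[dialect["animal_id"]].astype(str)
        if dialect["animal_id"] in raw.columns
        else (animal_id or "unknown")
    )
    df["kind"] = raw[dialect["kind"]].astype(str).str.strip().str.lower()
    bad_kind = ~df["kind"].isin(["dive", "surface"])
    if bad_kind.any():
        raise ValueError(
            f"unrecognized record type(s) {sorted(df.loc[bad_kind, 'kind'].unique())}"
        )
    for key in ("start", "end"):
        try:
            df[key] = pd.to_datetime(raw[dialect[key]], utc=True).dt.tz_localize(None)
        except (ValueError, TypeError) as exc:
            bad = pd.to_datetime(raw[dialect[key]], utc=True, errors="coerce").isna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else -1
            raise ValueError(
                f"unparseable {key!r} timestamp at row {row}: {exc}"
            ) from exc

    for key in ("depth_min", "depth_max", "dur_min", "dur_max"):
        df[key] = pd.to_numeric(raw[dialect[key]], errors="coerce")
    if dialect["shape"] in raw.columns:
        shape = raw[dialect["shape"]].astype(str).str.strip().str.lower()
        shape = shape.replace({"": "none", "nan": "none"})
    else:
        shape = pd.Series("none", index=raw.index)
    df["shape"] = np.where(df["kind"] == "surface", "none", shape)

    # Analysis values: the means of the reported min/max brackets.
    df["depth"] = (df["depth_min"] + df["depth_max"]) / 2.0
    df["duration"] = (df["dur_min"] + df["dur_max"]) / 2.0
    df.loc[df["kind"] == "surface", ["depth_min", "depth_max", "depth"]] = np.nan
    # Surface durations may be reported only by start/end.
    missing_dur = df["duration"].isna()
    df.loc[missing_dur, "duration"] = (
        (df.loc[missing_dur, "end"] - df.loc[missing_dur, "start"]).dt.total_seconds()
    )

    out_of_order = (df["start"].diff().dt.total_seconds() < 0).sum()
    if out_of_order:
        logger.warning("behavior log had %d out-of-order rows; sorted by start", out_of_order)
    df = df.sort_values("start", kind="mergesort").reset_index(drop=True)
    return df[RECORD_COLUMNS]


def qc_behavior_log(records: pd.DataFrame,
                    max_plausible_depth_m: float = 3000.0,
                    duration_tolerance_s: float = 60.0,
                    drift_window: int = 20,
                    drift_rate_m_per_day: float = 2.0) -> dict:
    """Screen a behavior log for transducer failures, drift, and bookkeeping faults.

    Returns a report dict with per-record boolean flag arrays and a
    deployment-level ``verdict`` ("pass" if no critical flag fires).
    Flags:

    - ``implausible_depth``: negative depth estimates, or deeper than
      ``max_plausible_depth_m``;
    - ``duration_mismatch``: |reported duration - (end - start)| beyond
      tolerance;
    - ``overlap``: record starts before the previous record ends;
    - ``drift`` (deployment-level): the rolling minimum of reported dive
      depths trends upward faster than ``drift_rate_m_per_day`` — a proxy for
      a drifting pressure transducer baseline.
    """
    if records.empty:
        raise ValueError("empty record table")
    df = records
    dives = df["kind"] == "dive"

    implausible = dives & (
        (df["depth_min"] < 0) | (df["depth_max"] > max_plausible_depth_m)
    )
    span_s = (df["end"] - df["start"]).dt.total_seconds()
    mismatch = (df["duration"] - span_s).abs() > duration_tolerance_s
    overlap = df["start"] < df["end"].shift()
    overlap = overlap.fillna(False)

    drift = False
    drift_slope = 0.0
    dive_df = df[dives]
    if len(dive_df) >= drift_window:
        roll_min = dive_df["depth"].rolling(drift_window, min_periods=drift_window).min().dropna()
        t_days = (
            dive_df.loc[roll_min.index, "start"] - dive_df["start"].iloc[0]
        ).dt.total_seconds() / 86400.0
        if t_days.nunique() > 1:
            drift_slope = float(np.polyfit(t_days, roll_min, 1)[0])
            drift = drift_slope > drift_rate_m_per_day

    n_critical = int(implausible.sum()) + int(overlap.sum()) + int(drift)
    return {
        "implausible_depth": implausible.to_numpy(),
        "duration_mismatch": mismatch.to_numpy(),
        "overlap": overlap.to_numpy(),
        "drift": bool(drift),
        "drift_slope_m_per_day": drift_slope,
        "verdict": "pass" if n_critical == 0 else "fail",
        "n_flags": n_critical + int(mismatch.sum()),
    }


@dataclass
class StandardizedLog:
    """A behavior log standardized to common dive thresholds."""

    records: pd.DataFrame
    depth_threshold: float = DEPTH_THRESHOLD_M
    duration_threshold: float = DURATION_THRESHOLD_S
    coverage: float | None = None

    @property
    def dives(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "dive"].reset_index(drop=True)

    @property
    def n_dives(self) -> int:
        return int((self.records["kind"] == "dive").sum())

    def total_covered_s(self) -> float:
        return float(self.records["duration"].sum())


def _check_non_overlapping(df: pd.DataFrame) -> None:
    prev_end = df["end"].shift()
    bad = df["start"] < prev_end
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"overlapping records at rows {i - 1} and {i}: "
            f"{df['end'].iloc[i - 1]} > {df['start'].iloc[i]}"
        )


def standardize(records: pd.DataFrame,
                depth_threshold: float = DEPTH_THRESHOLD_M,
                duration_threshold: float = DURATION_THRESHOLD_S) -> StandardizedLog:
    """Apply the common dive definition and merge surface runs.

    A record stays a dive iff ``depth >= depth_threshold`` AND
    ``duration >= duration_threshold``; all other dive records are
    reclassified as surface periods.  Consecutive surface records (original
    or reclassified) are merged into single records spanning their union.
    Total covered time is conserved exactly.
    """
    if records.empty:
        return StandardizedLog(records.copy(), depth_threshold, duration_threshold)
    df = records.sort_values("start", kind="mergesort").reset_index(drop=True)
    _check_non_overlapping(df)

    is_dive = (
        (df["kind"] == "dive")
        & (df["depth"] >= depth_threshold)
        & (df["duration"] >= duration_threshold)
    )
    df = df.copy()
    df.loc[~is_dive, "kind"] = "surface"
    df.loc[~is_dive, ["depth_min", "depth_max", "depth"]] = np.nan
    df.loc[~is_dive, "shape"] = "none"

    # Merge runs of consecutive surface records per animal.
    merged_rows = []
    for animal, sub in df.groupby("animal_id", sort=False):
        run: list[int] = []
        for idx in list(sub.index) + [None]:
            if idx is not None and sub.loc[idx, "kind"] == "surface":
                run.append(idx)
                continue
            if run:
                block = sub.loc[run]
                merged_rows.append({
                    "animal_id": animal, "kind": "surface",
                    "start": block["start"].min(), "end": block["end"].max(),
                    "depth_min": np.nan, "depth_max": np.nan,
                    "dur_min": np.nan, "dur_max": np.nan, "shape": "none",
                    "depth": np.nan, "duration": float(block["duration"].sum()),
                })
                run = []
            if idx is not None:
                merged_rows.append(sub.loc[idx].to_dict())
    out = pd.DataFrame(merged_rows, columns=RECORD_COLUMNS)
    out = out.sort_values(["animal_id", "start"], kind="mergesort").reset_index(drop=True)
    return StandardizedLog(out, depth_threshold, duration_threshold)


def coverage(records: pd.DataFrame, span_start, span_end) -> float:
    """Fraction of [span_start, span_end] covered by record durations.

    Record intervals are clipped to the span; the summed clipped durations
    divided by the span length gives a value in [0, 1].
    """
    span_start, span_end = pd.Timestamp(span_start), pd.Timestamp(span_end)
    if span_end <= span_start:
        raise ValueError("span_end must be after span_start")
    start = records["start"].clip(lower=span_start)
    end = records["end"].clip(upper=span_end)
    covered = (end - start).dt.total_seconds().clip(lower=0.0).sum()
    return float(min(covered / (span_end - span_start).total_seconds(), 1.0))
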