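"""Time-depth-recorder (TDR) processing: 1-Hz depth series to dive tables.

Archival TDR tags sample depth once per second.  The pressure sensor baseline
drifts with temperature, so the series is first zero-offset corrected against
a rolling surface baseline.  Dives are then maximal excursions at or beyond a
detection threshold (default 10 m, about two body lengths for a mid-sized
delphinid), summarized by maximum depth, duration, bottom time (time at >=
80% of maximum depth), descent/ascent rates, and a shape code derived from
the bottom-time fraction of dive duration:

    square : bottom fraction > 0.5
    u      : 0.2 < bottom fraction <= 0.5
    v      : bottom fraction <= 0.2
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIVE_THRESHOLD_M = 10.0
BOTTOM_FRACTION_OF_MAX = 0.8


@dataclass
class TDRProfile:
    """A 1-Hz depth series for one animal.

    ``time`` is a pandas DatetimeIndex at a fixed 1-second step; ``depth`` is
    meters, positive down; ``velocity`` is optional uncalibrated relative
    swim speed.
    """

    animal_id: str
    time: pd.DatetimeIndex
    depth: np.ndarray
    velocity: np.ndarray | None = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.time) != len(self.depth):
            raise ValueError("time and depth lengths differ")
        steps = np.diff(self.time.view("int64"))
        if len(steps) and (steps <= 0).any():
            raise ValueError("time must be strictly increasing")


def classify_shape(bottom_fraction: float) -> str:
    """Map a bottom-time fraction to the square/u/v shape code."""
    if bottom_fraction > 0.5:
        return "square"
    if bottom_fraction > 0.2:
        return "u"
    return "v"


def zero_offset_correct(profile: TDRProfile, window_min: float = 30.0,
                        surface_quantile: float = 0.1,
                        shallow_cutoff_m: float = 15.0) -> TDRProfile:
    """Remove a slowly varying surface baseline from a depth series.

    Within rolling windows, the baseline is estimated as a low quantile of
    the readings shallower than ``shallow_cutoff_m`` (surface intervals),
    linearly interpolated across windows with no surface time, and subtracted.
    Small negative residuals are clipped to zero.
    """
    n_per_window = int(round(window_min * 60.0))
    if n_per_window < 2:
        raise ValueError("window must span at least 2 samples")
    depth = profile.depth
    n = len(depth)
    centers, baselines = [], []
    for start in range(0, n, n_per_window):
        chunk = depth[start:start + n_per_window]
        shallow = chunk[chunk <= shallow_cutoff_m]
        if len(shallow) >= 10:
            centers.append(start + len(chunk) / 2.0)
            baselines.append(np.quantile(shallow, surface_quantile))
    if not centers:
        # No surface time at all: fall back to a global minimum offset.
        baseline = np.full(n, depth.min())
    else:
        baseline = np.interp(np.arange(n), centers, baselines)
    corrected = np.clip(depth - baseline, 0.0, None)
    return TDRProfile(profile.animal_id, profile.time, corrected, profile.velocity)


def detect_dives(profile: TDRProfile, threshold: float = DIVE_THRESHOLD_M,
                 sensor_ceiling_m: float | None = None,
                 include_partial: bool = False) -> pd.DataFrame:
    """Extract dives from a corrected profile.

    A dive is a maximal run of samples with depth >= ``threshold``.  Per
    dive: start/end, max depth, duration, bottom time (samples at >= 80% of
    the dive's max depth), descent rate (depth gain from dive start to the
    first bottom-phase sample over elapsed time), ascent rate (analogous),
    and the shape code.  Dives truncated by the record edge are flagged
    ``partial`` and excluded unless ``include_partial``.  Dives reaching
    within 2 m of ``sensor_ceiling_m`` are flagged ``saturated`` (their depth
    is a lower bound; exclude from depth summaries downstream).
    """
    depth = profile.depth
    time = profile.time
    in_dive = depth >= threshold
    if not in_dive.any():
        return pd.DataFrame(columns=[
            "animal_id", "start", "end", "max_depth", "duration",
            "bottom_time", "descent_rate", "ascent_rate", "shape",
            "partial", "saturated",
        ])
    edges = np.diff(in_dive.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))  # inclusive last in-dive index
    if in_dive[0]:
        starts = [0] + starts
    if in_dive[-1]:
        ends = ends + [len(depth) - 1]

    step_s = float(np.median(np.diff(time.view("int64")))) / 1e9
    rows = []
    for s, e in zip(starts, ends):
        seg = depth[s:e + 1]
        max_depth = float(seg.max())
        partial = (s == 0) or (e == len(depth) - 1)
        # Duration spans the threshold crossings; with 1-Hz sampling the
        # interval [s, e] contains e - s + 1 samples, each representing one
        # sampling step.
        duration = (e - s + 1) * step_s
        bottom_mask = seg >= BOTTOM_FRACTION_OF_MAX * max_depth
        bottom_time = float(bottom_mask.sum() * step_s)
        b_idx = np.flatnonzero(bottom_mask)
        first_b, last_b = int(b_idx[0]), int(b_idx[-1])
        descent_rate = (seg[first_b] - seg[0]) / (first_b * step_s) if first_b > 0 else 0.0
        n_after = len(seg) - 1 - last_b
        ascent_rate = (seg[last_b] - seg[-1]) / (n_after * step_s) if n_after > 0 else 0.0
        saturated = (
            sensor_ceiling_m is not None and max_depth >= sensor_ceiling_m - 2.0
        )
        rows.append({
            "animal_id": profile.animal_id,
            "start": time[s], "end": time[e],
            "max_depth": max_depth, "duration": duration,
            "bottom_time": bottom_time,
            "descent_rate": max(descent_rate, 0.0),
            "ascent_rate": max(ascent_rate, 0.0),
            "shape": classify_shape(bottom_time / duration),
            "partial": partial, "saturated": bool(saturated),
        })
    out = pd.DataFrame(rows)
    if not include_partial:
        out = out[~out["partial"]].reset_index(drop=True)
    return out


def time_at_depth(profile: TDRProfile, bin_edges) -> pd.DataFrame:
    """Proportion of samples in each depth bin.

    ``bin_edges`` are ascending inner edges in meters; bins are
    [e0, e1), [e1, e2), ..., [e_last, inf).  Proportions sum to 1 exactly.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    full_edges = np.concatenate([edges, [np.inf]])
    counts, _ = np.histogram(profile.depth, bins=full_edges)
    # histogram drops values below the first edge; fold them into bin 0.
    counts[0] += int((profile.depth < edges[0]).sum())
    props = counts / len(profile.depth)
    labels = [
        f"[{full_edges[i]:g},{full_edges[i+1]:g})" for i in range(len(counts))
    ]
    return pd.DataFrame({"bin": labels, "proportion": props})
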