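"""TDR processing: zero-offset correction, dive detection, shapes, time-at-depth."""

import numpy as np
import pandas as pd
import pytest

from divetrace import tdr
from divetrace.synthetic import simulate_tdr_profile


def _profile(depths, animal_id="T", start="2024-01-01"):
    time = pd.date_range(start, periods=len(depths), freq="1s")
    return tdr.TDRProfile(animal_id, time, np.asarray(depths, float))


def triangle(max_depth=100.0, rate=1.0):
    """Symmetric V dive flanked by surface time."""
    up = np.arange(0.0, max_depth, rate)
    return np.concatenate([np.zeros(60), up, [max_depth], up[::-1], np.zeros(60)])


def trapezoid(max_depth=80.0, ramp_s=40, hold_s=300):
    ramp = np.linspace(0.0, max_depth, ramp_s, endpoint=False)
    return np.concatenate([np.zeros(60), ramp, np.full(hold_s, max_depth),
                           ramp[::-1], np.zeros(60)])


class TestZeroOffset:
    def test_constant_offset_removed(self):
        depths = triangle() + 3.0
        prof = tdr.zero_offset_correct(_profile(np.tile(depths, 8)))
        surface = prof.depth[prof.depth < 10]
        assert abs(np.median(surface)) <= 0.5

    def test_planted_linear_drift_recovered(self):
        # 0 -> 5 m drift over 10 h on a series of known 60-m dives.
        block = np.concatenate([np.zeros(1500), trapezoid(60.0), np.zeros(1500)])
        base = np.tile(block, int(np.ceil(36000 / len(block))))[:36000]
        drift = np.linspace(0.0, 5.0, 36000)
        prof = tdr.zero_offset_correct(_profile(base + drift))
        dives = tdr.detect_dives(prof)
        assert len(dives) > 0
        assert np.allclose(dives["max_depth"], 60.0, atol=1.0)

    def test_already_zeroed_unchanged(self):
        base = np.tile(triangle(), 10)
        prof = tdr.zero_offset_correct(_profile(base))
        assert np.max(np.abs(prof.depth - base)) <= 0.5

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            tdr.zero_offset_correct(_profile(np.zeros(100)), window_min=0.01)


class TestDetectDives:
    def test_triangle_analytic(self):
        dives = tdr.detect_dives(_profile(triangle(100.0, 1.0)))
        assert len(dives) == 1
        d = dives.iloc[0]
        assert d["max_depth"] == 100.0
        # In-dive samples: depth >= 10 on both flanks plus the apex.
        assert d["duration"] == pytest.approx(181.0)
        # Bottom: samples >= 80 m -> 80..100..80 = 41 samples.
        assert d["bottom_time"] == pytest.approx(41.0)
        assert d["descent_rate"] == pytest.approx(1.0, rel=0.05)
        assert d["ascent_rate"] == pytest.approx(1.0, rel=0.05)
        # 41/181 = 0.227 -> u under the strict >20% rule.
        assert d["shape"] == "u"

    def test_trapezoid_is_square(self):
        dives = tdr.detect_dives(_profile(trapezoid(80.0, 40, 300)))
        d = dives.iloc[0]
        assert d["max_depth"] == 80.0
        assert d["shape"] == "square"
        assert d["bottom_time"] / d["duration"] > 0.5

    def test_sharp_v_shape(self):
        # Slow shallow phases with a brief deep spike: bottom fraction << 0.2.
        # (A symmetric triangle sits exactly at the 20% boundary: time at
        # >=80% of max is 0.2*max/(max - threshold) of the dive duration.)
        depths = np.concatenate([
            np.zeros(30), np.linspace(0, 30, 300), np.linspace(30, 200, 60),
            np.linspace(200, 30, 60), np.linspace(30, 0, 300), np.zeros(30)])
        dives = tdr.detect_dives(_profile(depths))
        d = dives.iloc[0]
        assert d["shape"] == "v"
        assert d["bottom_time"] / d["duration"] < 0.1

    def test_shallow_profile_yields_no_dives(self):
        depths = 9.0 * np.abs(np.sin(np.linspace(0, 20, 5000)))
        assert len(tdr.detect_dives(_profile(depths))) == 0

    def test_edge_truncated_dive_flagged_partial(self):
        depths = np.concatenate([np.full(100, 50.0), np.zeros(100)])
        full = tdr.detect_dives(_profile(depths), include_partial=True)
        assert full.iloc[0]["partial"]
        assert len(tdr.detect_dives(_profile(depths))) == 0

    def test_saturated_dive_flagged(self):
        dives = tdr.detect_dives(_profile(trapezoid(233.5, 100, 60)),
                                 sensor_ceiling_m=234.0)
        assert dives.iloc[0]["saturated"]

    def test_time_shift_invariance(self):
        a = tdr.detect_dives(_profile(triangle(), start="2024-01-01"))
        b = tdr.detect_dives(_profile(triangle(), start="2024-06-15 13:37"))
        for col in ("max_depth", "duration", "bottom_time", "shape"):
            assert (a[col] == b[col]).all()

    def test_shape_tie_rules(self):
        assert tdr.classify_shape(0.5) == "u"
        assert tdr.classify_shape(0.2) == "v"
        assert tdr.classify_shape(0.50001) == "square"
        assert tdr.classify_shape(0.20001) == "u"

    def test_matches_bruteforce_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = 2000
            depth = np.clip(np.cumsum(rng.normal(0, 1.5, n)) + 5.0, 0.0, None)
            depth[:30] = 0.0
            depth[-30:] = 0.0
            prof = _profile(depth)
            dives = tdr.detect_dives(prof)
            # Brute force: segment scan.
            mask = depth >= 10.0
            expected = []
            i = 0
            while i < n:
                if mask[i]:
                    j = i
                    while j < n and mask[j]:
                        j += 1
                    seg = depth[i:j]
                    md = seg.max()
                    bt = int((seg >= 0.8 * md).sum())
                    expected.append((md, j - i, bt,
                                     tdr.classify_shape(bt / (j - i))))
                    i = j
                else:
                    i += 1
            got = list(zip(dives["max_depth"], dives["duration"].astype(int),
                           dives["bottom_time"].astype(int), dives["shape"]))
            assert got == [(md, dur, bt, sh) for md, dur, bt, sh in expected]

    def test_duration_accounting_conserved(self):
        depth = np.tile(trapezoid(), 5)
        prof = _profile(depth)
        dives = tdr.detect_dives(prof)
        in_dive = int((depth >= 10.0).sum())
        assert dives["duration"].sum() == pytest.approx(in_dive)


class TestTimeAtDepth:
    def test_all_surface(self):
        out = tdr.time_at_depth(_profile(np.zeros(500)), [0, 10, 50])
        assert list(out["proportion"]) == [1.0, 0.0, 0.0]

    def test_known_occupancy_exact(self):
        depth = np.concatenate([np.full(300, 5.0), np.full(100, 30.0),
                                np.full(100, 80.0)])
        out = tdr.time_at_depth(_profile(depth), [0, 10, 50])
        assert list(out["proportion"]) == [0.6, 0.2, 0.2]
        assert out["proportion"].sum() == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        depth = rng.uniform(0, 300, 1000)
        a = tdr.time_at_depth(_profile(depth), [0, 10, 50, 100])
        b = tdr.time_at_depth(_profile(rng.permutation(depth)), [0, 10, 50, 100])
        assert np.allclose(a["proportion"], b["proportion"])

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            tdr.time_at_depth(_profile(np.zeros(10)), [50, 10])


class TestSyntheticTDR:
    def test_generator_truth_linkage(self):
        prof, truth = simulate_tdr_profile(duration_h=4.0, seed=9, noise_sd_m=0.0)
        dives = tdr.detect_dives(prof)
        deep_truth = truth[truth["max_depth"] >= 10.0]
        assert len(dives) == len(deep_truth)
        assert np.allclose(np.sort(dives["max_depth"]),
                           np.sort(deep_truth["max_depth"]), atol=1.0)

    def test_same_seed_identical(self):
        p1, _ = simulate_tdr_profile(duration_h=2.0, seed=3)
        p2, _ = simulate_tdr_profile(duration_h=2.0, seed=3)
        assert np.array_equal(p1.depth, p2.depth)
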