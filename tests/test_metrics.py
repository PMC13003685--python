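"""Dive rates, hour units, and median-of-individuals group summaries."""

import numpy as np
import pandas as pd
import pytest

from divetrace import metrics
from conftest import make_records

HON = (-157.85, 21.3)


def _fixed_lookup(animal_id, times):
    return (np.full(len(times), HON[0]), np.full(len(times), HON[1]))


def _alternating_log(start="2024-03-01 00:00:00", n_dives=12, dive_s=600,
                     surface_s=6600, animal_id="A"):
    rows = []
    t = pd.Timestamp(start)
    for _ in range(n_dives):
        rows.append(("dive", t, dive_s, 200.0))
        t += pd.Timedelta(seconds=dive_s)
        rows.append(("surface", t, surface_s, np.nan))
        t += pd.Timedelta(seconds=surface_s)
    return make_records(rows, animal_id=animal_id)


class TestDiveRate:
    def test_twelve_dives_over_24h(self):
        recs = _alternating_log()  # 12 * (600 + 6600) s = 24 h
        out = metrics.dive_rate(recs, "overall")
        assert out["rate_per_h"].iloc[0] == pytest.approx(0.5)

    def test_gap_shrinks_denominator(self):
        recs = _alternating_log()
        # Delete 6 h of surface records (3 surface rows of 6600 s != 6 h;
        # delete surface rows totalling exactly 6 h instead: 6*3600/6600).
        surf_idx = recs.index[recs["kind"] == "surface"][:3]
        removed_s = recs.loc[surf_idx, "duration"].sum()
        gappy = recs.drop(surf_idx)
        out = metrics.dive_rate(gappy, "overall")
        expect = 12 / ((24 * 3600 - removed_s) / 3600)
        assert out["rate_per_h"].iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_category_rates_recombine_to_total_dives(self):
        recs = _alternating_log(n_dives=30, surface_s=3000)
        d = metrics.split_records(recs, "diel", position_lookup=_fixed_lookup)
        rates = metrics.dive_rate(d, "diel_category")
        total = (rates["rate_per_h"] * rates["covered_hours"]).sum()
        assert total == pytest.approx(30, abs=1e-9)

    def test_empty_group_rate_undefined_not_zero(self):
        recs = _alternating_log(n_dives=2)
        recs["diel"] = ["day", "day", "night", "night"]
        recs.loc[recs["diel"] == "night", "duration"] = 0.0
        out = metrics.dive_rate(recs, "diel_category").set_index("diel")
        assert np.isnan(out.loc["night", "rate_per_h"])
        assert bool(out.loc["night", "undefined"])


class TestHourUnits:
    def test_full_hour_with_two_dives(self):
        rows = [
            ("dive", "2024-03-01 10:05:00", 300, 200.0),
            ("surface", "2024-03-01 10:10:00", 600, np.nan),
            ("dive", "2024-03-01 10:20:00", 300, 200.0),
            ("surface", "2024-03-01 10:25:00", 2100, np.nan),
        ]
        recs = make_records(rows)
        # Pad to fill the 10:00-11:00 UTC hour exactly (00:00-01:00 HST).
        pad = make_records([("surface", "2024-03-01 10:00:00", 300, np.nan)])
        recs = pd.concat([pad, recs], ignore_index=True)
        split = metrics.split_records(recs, "clock_hour")
        units = metrics.build_hour_units(split)
        assert len(units) == 1
        assert units["n_dives"].iloc[0] == 2
        assert units["covered_hours"].iloc[0] == pytest.approx(1.0)

    def test_half_covered_hour_dropped(self):
        recs = make_records([("surface", "2024-03-01 10:00:00", 1800, np.nan)])
        split = metrics.split_records(recs, "clock_hour")
        units = metrics.build_hour_units(split)
        assert len(units) == 0
        kept = metrics.build_hour_units(split, keep_dropped=True)
        assert len(kept) == 1 and not kept["retained"].iloc[0]

    def test_48h_log_matches_hand_enumeration(self):
        recs = _alternating_log(n_dives=24)  # 48 h, one dive every 2 h
        split = metrics.split_records(recs, "clock_hour")
        units = metrics.build_hour_units(split, keep_dropped=True)
        # 48 full hours; dives start at 00:00, 02:00, ... UTC.
        assert len(units) == 48
        assert units["covered_hours"].sum() == pytest.approx(48.0)
        assert units["n_dives"].sum() == 24
        # Dive starts at even UTC hours = even-ish HST hours shifted by -10.
        by_hour = units.groupby("hour")["n_dives"].sum()
        expect_hours = sorted({(h - 10) % 24 for h in range(0, 48, 2)})
        assert sorted(by_hour[by_hour > 0].index) == expect_hours

    def test_pooling_identity_with_dropped_units(self, small_scenario):
        from divetrace import behavior_log as bl
        aid = "Tag001"
        std = bl.standardize(small_scenario.behavior_logs[aid])
        split = metrics.split_records(std.records, "clock_hour")
        units = metrics.build_hour_units(split, keep_dropped=True)
        assert units["n_dives"].sum() == std.n_dives


class TestGroupSummary:
    def test_two_animal_hand_calculation(self):
        df = pd.DataFrame({
            "animal_id": ["A"] * 3 + ["B"] * 3,
            "depth": [90.0, 100.0, 110.0, 290.0, 300.0, 310.0],
        })
        out = metrics.group_summary(df, "depth")
        assert out["grand_mean"].iloc[0] == pytest.approx(200.0)
        assert out["sd"].iloc[0] == pytest.approx(141.42, abs=0.01)
        assert out["cv_percent"].iloc[0] == pytest.approx(70.71, abs=0.01)

    def test_identical_animals_zero_cv(self):
        df = pd.DataFrame({"animal_id": ["A", "B"], "depth": [100.0, 100.0]})
        out = metrics.group_summary(df, "depth")
        assert out["cv_percent"].iloc[0] == 0.0

    def test_single_animal_sd_absent(self):
        df = pd.DataFrame({"animal_id": ["A"], "depth": [100.0]})
        out = metrics.group_summary(df, "depth")
        assert np.isnan(out["sd"].iloc[0])

    def test_median_based_invariance_to_row_duplication(self):
        df = pd.DataFrame({
            "animal_id": ["A"] * 3 + ["B"] * 3,
            "depth": [90.0, 100.0, 110.0, 290.0, 300.0, 310.0],
        })
        dup = pd.concat([df, df[df["animal_id"] == "A"]], ignore_index=True)
        a = metrics.group_summary(df, "depth")
        b = metrics.group_summary(dup.sample(frac=1, random_state=0), "depth")
        assert a["grand_mean"].iloc[0] == b["grand_mean"].iloc[0]

    def test_shape_proportions(self):
        df = pd.DataFrame({
            "animal_id": ["A"] * 4 + ["B"] * 2,
            "shape": ["square", "square", "u", "v", "u", "u"],
        })
        out = metrics.group_summary(df, "shape_proportions")
        u = out[out["shape"] == "u"].iloc[0]
        assert u["grand_mean"] == pytest.approx((0.25 + 1.0) / 2)

    def test_depth_bin_convention(self):
        assert metrics.depth_bin_label(75.0) == 100
        assert metrics.depth_bin_label(150.0) == 200
        assert metrics.depth_bin_label(100.0) == 100


class TestInterdiveSurface:
    def test_simple_between_dive_durations(self):
        recs = _alternating_log(n_dives=4)
        out = metrics.interdive_surface_durations(recs)
        assert len(out) == 3
        assert np.allclose(out["surface_s"], 6600.0)

    def test_gap_censors_interval(self):
        recs = _alternating_log(n_dives=3)
        surf_idx = recs.index[recs["kind"] == "surface"][0]
        recs.loc[surf_idx, "duration"] = 6600.0 - 1200.0  # 20-min hidden gap
        out = metrics.interdive_surface_durations(recs, max_gap_tolerance_s=600)
        assert len(out) == 1
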