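"""Dynamicity summaries, dividing-cell analyses, and the arc path model."""

import math

import numpy as np
import pytest

from caliberkit.dynamics import (
    DynamicitySummary,
    SeriesUnmeasurable,
    arc_path_ratio,
    border_to_border,
    dynamicity,
    group_by_region,
    pair_days,
    pearling_index,
    round_flat_pairing,
    select_round_flat,
)
from caliberkit.measure import CaliberMeasurement, CaliberSeries
from caliberkit.pipeline import two_level_sequence


def series_from(values, mode="time", flags=None):
    flags = flags or [False] * len(values)
    ms = [
        CaliberMeasurement(v, (-v / 2, v / 2), i, float(i) if mode == "lengthwise" else 3.0, f)
        for i, (v, f) in enumerate(zip(values, flags))
    ]
    return CaliberSeries(ms, mode)


class TestDynamicity:
    def test_hand_arithmetic(self):
        s = dynamicity(series_from([0.2, 0.3, 0.4]))
        assert s.mean_caliber_um == pytest.approx(0.3)
        assert s.sd_um == pytest.approx(0.1)
        assert s.rsd_percent == pytest.approx(100 / 3, abs=0.01)

    def test_constant_series(self):
        s = dynamicity(series_from([0.3, 0.3, 0.3, 0.3]))
        assert s.sd_um == 0.0 and s.rsd_percent == 0.0

    def test_rsd_scale_invariant(self):
        a = dynamicity(series_from([0.2, 0.3, 0.4]))
        b = dynamicity(series_from([0.4, 0.6, 0.8]))
        assert b.rsd_percent == pytest.approx(a.rsd_percent)
        assert b.sd_um == pytest.approx(2 * a.sd_um)

    def test_too_few_usable_frames(self):
        with pytest.raises(SeriesUnmeasurable):
            dynamicity(series_from([0.3, 0.3, 0.3], flags=[False, True, True]))


class TestPairDays:
    @staticmethod
    def summary(rsd, excluded=False):
        return DynamicitySummary(0.3, rsd * 0.3 / 100, rsd, 10, excluded)

    def test_decreased_count(self):
        day1 = {f"loc{i}": self.summary(28.0) for i in range(11)}
        day2 = {f"loc{i}": self.summary(20.0) for i in range(10)}
        day2["loc10"] = self.summary(30.0)  # the one location that increases
        tab = pair_days(day1, day2)
        assert (tab["delta"] < 0).sum() == 10
        assert len(tab) == 11

    def test_identical_days_zero_deltas(self):
        d = {f"loc{i}": self.summary(25.0) for i in range(4)}
        assert np.allclose(pair_days(d, d)["delta"], 0.0)

    def test_excluded_location_dropped(self):
        day1 = {"a": self.summary(28.0), "b": self.summary(26.0)}
        day2 = {"a": self.summary(20.0), "b": self.summary(19.0, excluded=True)}
        tab = pair_days(day1, day2)
        assert list(tab["location"]) == ["a"]

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            pair_days({"a": self.summary(28.0)}, {"b": self.summary(20.0)})


class TestPearling:
    def test_constant_profile_zero(self):
        assert pearling_index(series_from([0.25] * 6, mode="lengthwise")) == 0.0

    def test_translation_invariant(self):
        base = [0.2, 0.35, 0.3, 0.5, 0.25]
        a = pearling_index(series_from(base, mode="lengthwise"))
        b = pearling_index(series_from([v + 0.1 for v in base], mode="lengthwise"))
        assert b == pytest.approx(a)

    def test_matches_numpy_sample_sd(self):
        vals = [0.2, 0.35, 0.3, 0.5, 0.25]
        assert pearling_index(series_from(vals, mode="lengthwise")) == pytest.approx(
            np.std(vals, ddof=1)
        )


class TestTwoLevelSequence:
    @pytest.mark.parametrize("target", [10.0, 30.0, 60.0])
    def test_exact_sample_rsd(self, target):
        c = two_level_sequence(0.45, target, 12)
        assert np.mean(c) == pytest.approx(0.45)
        assert 100 * np.std(c, ddof=1) / np.mean(c) == pytest.approx(target)
        assert c.min() > 0.2  # stays resolvable even at 60% RSD


class TestGroupByRegion:
    def test_grouping_and_flag_filter(self):
        series = series_from([0.2, 0.3, 0.4, 0.5], mode="lengthwise",
                             flags=[False, False, True, False])
        g = group_by_region(series, ["neighbor1", "dividing", "dividing", "neighbor2"])
        assert np.allclose(g["neighbor1"], [0.2])
        assert np.allclose(g["dividing"], [0.3])  # flagged station dropped
        assert np.allclose(g["neighbor2"], [0.5])

    def test_empty_region_reported_empty(self):
        series = series_from([0.2, 0.3], mode="lengthwise")
        g = group_by_region(series, ["dividing", "dividing"])
        assert g["neighbor1"].size == 0

    def test_label_alignment_enforced(self):
        with pytest.raises(ValueError):
            group_by_region(series_from([0.2, 0.3], mode="lengthwise"), ["dividing"])


class TestBorderToBorder:
    RECT = [(4.0, 0.0), (16.0, 0.0), (16.0, 6.0), (4.0, 6.0)]

    def test_straight_crossing(self):
        # straight axon across a 12 µm wide cell
        assert border_to_border([(0, 3.0), (20, 3.0)], self.RECT) == pytest.approx(12.0)

    def test_rigid_rotation_invariant(self):
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        axon = np.array([(0, 3.0), (20, 3.0)]) @ rot.T
        rect = np.array(self.RECT) @ rot.T
        assert border_to_border(axon, rect) == pytest.approx(12.0, abs=1e-9)

    def test_too_few_crossings(self):
        with pytest.raises(ValueError):
            border_to_border([(0, 3.0), (10, 3.0)], self.RECT)  # ends inside


class TestSelectRoundFlat:
    def test_documented_example(self):
        sel = select_round_flat([8.0, 8.2, 11.5, 12.0])
        assert (sel.round_frame, sel.flat_frame) == (1, 2)
        assert sel.max_increase_um == pytest.approx(3.3)

    def test_tie_takes_earliest_and_flags(self):
        sel = select_round_flat([8.0, 9.0, 10.0, 11.0])
        assert (sel.round_frame, sel.flat_frame) == (0, 1)
        assert sel.tie_flag

    def test_decreasing_sequence_least_negative(self):
        sel = select_round_flat([12.0, 11.0, 10.5, 9.0])
        assert (sel.round_frame, sel.flat_frame) == (1, 2)

    def test_equals_exhaustive_scan(self, rng):
        for _ in range(30):
            lengths = rng.uniform(6, 14, size=rng.integers(2, 9))
            sel = select_round_flat(lengths)
            diffs = [lengths[i + 1] - lengths[i] for i in range(len(lengths) - 1)]
            assert sel.round_frame == int(np.argmax(diffs))


class TestRoundFlatPairing:
    def test_identical_frames_zero_differences(self):
        s = series_from([0.3, 0.32, 0.28, 0.31], mode="lengthwise")
        regions = ["dividing"] * 4
        out = round_flat_pairing(s, s, regions, regions)
        assert np.allclose(out["differences"], 0.0)
        assert out["pearling_round"] == pytest.approx(out["pearling_flat"])

    def test_station_leaving_territory_dropped(self):
        s_round = series_from([0.3, 0.32, 0.28], mode="lengthwise")
        s_flat = series_from([0.3, 0.31, 0.27], mode="lengthwise")
        out = round_flat_pairing(
            s_round, s_flat, ["dividing"] * 3, ["dividing", "neighbor1", "dividing"]
        )
        assert out["n_dropped"] == 1
        assert out["round"].size == 2


class TestArcModel:
    def test_flat_limit(self):
        m = arc_path_ratio(10.0, 0.0, 10.0)
        assert m.arc_length_um == 10.0 and m.path_ratio == 1.0

    def test_semicircle_closed_form(self):
        m = arc_path_ratio(10.0, 5.0, 10.0)
        assert m.arc_length_um == pytest.approx(5 * math.pi, rel=1e-12)
        assert m.path_ratio == pytest.approx(math.pi / 2, rel=1e-12)

    def test_matches_million_segment_polyline_oracle(self):
        chord, sag = 7.0, 2.0
        r = (chord**2 / 4 + sag**2) / (2 * sag)
        half = math.asin(chord / (2 * r))
        th = np.linspace(-half, half, 1_000_001)
        pts = np.column_stack([r * np.sin(th), r * np.cos(th)])
        oracle = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        m = arc_path_ratio(chord, sag, 10.0)
        assert m.arc_length_um == pytest.approx(oracle, rel=1e-6)
        assert m.path_ratio == pytest.approx(oracle / 10.0, rel=1e-6)

    def test_strictly_increasing_in_sagitta_and_continuous_at_zero(self):
        chord = 8.0
        sags = np.linspace(0.0, 6.0, 40)
        arcs = [arc_path_ratio(chord, s, 10.0).arc_length_um for s in sags]
        assert all(b > a for a, b in zip(arcs, arcs[1:]))
        assert arc_path_ratio(chord, 1e-9, 10.0).arc_length_um == pytest.approx(chord, abs=1e-6)

    def test_arc_never_shorter_than_chord(self):
        for s in (0.0, 0.5, 2.0, 5.0):
            assert arc_path_ratio(6.0, s, 8.0).arc_length_um >= 6.0 - 1e-12

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            arc_path_ratio(0.0, 1.0, 5.0)
        with pytest.raises(ValueError):
            arc_path_ratio(10.0, 1.0, 9.0)
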