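import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, Point, Polygon

from damcap import pipeline
from damcap.reaches import (
    flag_activity,
    mean_bankfull_width,
    segment_network,
    snap_observations,
)


def _line(length, y=0.0):
    return LineString([(0, y), (length, y)])


class TestSegmentation:
    @pytest.mark.parametrize(
        "length, n_parts, part_len",
        [(450, 3, 150.0), (199, 1, 199.0), (601, 4, 150.25), (200, 2, 100.0)],
    )
    def test_split_counts(self, length, n_parts, part_len):
        out = segment_network([_line(length)])
        assert len(out) == n_parts
        np.testing.assert_allclose(out["length_m"], part_len, rtol=1e-9)

    def test_zero_length_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-length"):
            out = segment_network([LineString([(0, 0), (0, 0)]), _line(50)])
        assert len(out) == 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.5, 2000), min_size=1, max_size=8))
    def test_length_conserved_and_all_short(self, lengths):
        lines = [_line(l, y=10 * i) for i, l in enumerate(lengths)]
        out = segment_network(lines)
        assert out["length_m"].sum() == pytest.approx(sum(lengths), rel=1e-6)
        assert (out["length_m"] < 200 + 1e-9).all()
        # parts of one parent are equal: group by y coordinate
        for i in range(len(lengths)):
            part = [g.length for g in out["geometry"] if g.coords[0][1] == 10 * i]
            np.testing.assert_allclose(part, part[0])


class TestBankfullWidth:
    def test_area_over_length(self):
        reach = _line(100)
        channel = Polygon([(0, -2), (100, -2), (100, 2), (0, 2)])
        w, capped = mean_bankfull_width(reach, channel)
        assert w == pytest.approx(4.0, rel=1e-6)
        assert not capped

    def test_no_channel_gives_declared_minimum(self):
        w, capped = mean_bankfull_width(_line(100), None)
        assert w == 0.5 and not capped

    def test_channel_wider_than_buffer_flagged(self):
        reach = _line(100)
        channel = Polygon([(-50, -30), (150, -30), (150, 30), (-50, 30)])
        w, capped = mean_bankfull_width(reach, channel)
        assert capped
        assert w == pytest.approx(2 * 20.0, rel=1e-6)  # capped at twice the buffer


class TestSnapping:
    def _reaches(self):
        return pd.DataFrame(
            {
                "reach_id": [0, 1],
                "geometry": [_line(100, y=0), _line(100, y=100)],
                "length_m": [100.0, 100.0],
            }
        )

    def test_nearest_reach_wins(self):
        pts = pd.DataFrame({"geometry": [Point(50, 3)], "kind": ["dam"]})
        out = snap_observations(pts, self._reaches())
        assert out.loc[0, "snapped_reach_id"] == 0
        assert out.loc[0, "snap_distance_m"] == pytest.approx(3.0)

    def test_equidistant_point_takes_lowest_id(self):
        pts = pd.DataFrame({"geometry": [Point(50, 50)], "kind": ["dam"]})
        out = snap_observations(pts, self._reaches())
        assert out.loc[0, "snapped_reach_id"] == 0

    def test_exclusion_mask_drops_and_counts(self):
        pts = pd.DataFrame(
            {"geometry": [Point(50, 3), Point(10, 1)], "kind": ["dam", "feeding_sign"]}
        )
        mask = [Polygon([(0, -5), (20, -5), (20, 5), (0, 5)])]
        out = snap_observations(pts, self._reaches(), exclusion_masks=mask)
        assert len(out) == 1
        assert out.attrs["excluded"] == 1

    def test_no_reaches_rejected(self):
        pts = pd.DataFrame({"geometry": [Point(0, 0)], "kind": ["dam"]})
        with pytest.raises(ValueError):
            snap_observations(pts, pd.DataFrame(columns=["reach_id", "geometry"]))


class TestActivity:
    def _snapped(self, rows):
        return pd.DataFrame(rows, columns=["geometry", "kind", "snapped_reach_id", "snap_distance_m"])

    def test_feeding_signs_activate_without_dams(self):
        reaches = pd.DataFrame({"reach_id": [0], "geometry": [_line(50)], "length_m": [50.0]})
        snapped = self._snapped(
            [(Point(1, 0), "feeding_sign", 0, 0.0), (Point(2, 0), "feeding_sign", 0, 0.0)]
        )
        out = flag_activity(reaches, snapped)
        assert bool(out.loc[0, "is_active"]) and out.loc[0, "observed_dams"] == 0

    def test_dam_counts(self):
        reaches = pd.DataFrame({"reach_id": [0], "geometry": [_line(50)], "length_m": [50.0]})
        out = flag_activity(reaches, self._snapped([(Point(1, 0), "dam", 0, 0.0)]))
        assert bool(out.loc[0, "is_active"]) and out.loc[0, "observed_dams"] == 1

    def test_removed_dams_activate_but_do_not_count(self):
        reaches = pd.DataFrame({"reach_id": [0], "geometry": [_line(50)], "length_m": [50.0]})
        out = flag_activity(reaches, self._snapped([(Point(1, 0), "removed_dam", 0, 0.0)]))
        assert bool(out.loc[0, "is_active"]) and out.loc[0, "observed_dams"] == 0

    def test_adding_points_never_deactivates(self):
        reaches = pd.DataFrame(
            {"reach_id": [0, 1], "geometry": [_line(50), _line(50, 10)], "length_m": [50.0, 50.0]}
        )
        one = self._snapped([(Point(1, 0), "dam", 0, 0.0)])
        two = pd.concat([one, self._snapped([(Point(1, 10), "feeding_sign", 1, 0.0)])])
        a1 = flag_activity(reaches, one)["is_active"]
        a2 = flag_activity(reaches, two)["is_active"]
        assert np.all(a2[a1] )

    def test_survey_fixture_totals(self):
        """89 dam points spread over the 58 fixture reaches tally exactly."""
        fx = pipeline.load_synthetic_survey_dams()
        reaches = pd.DataFrame(
            {
                "reach_id": np.arange(len(fx)),
                "geometry": [_line(100, y=10 * i) for i in range(len(fx))],
                "length_m": 100.0,
            }
        )
        rows = []
        for i, rec in fx.iterrows():
            for k in range(rec["dams"]):
                rows.append((Point(5 + k, 10 * i), "dam", i, 0.0))
        snapped = self._snapped(rows)
        out = flag_activity(reaches, snapped)
        assert out["observed_dams"].sum() == 89
        assert int((out["observed_dams"] > 0).sum()) == 58
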