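import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from damcap import forage, hydrology
from damcap.grid import template_like
from damcap.synthetic import (
    CatchmentScenario,
    generate_flows,
    generate_landcover,
    generate_terrain,
    simulate_observations,
    simulate_reach_table,
)

from conftest import graph_strahler_orders


class TestScenarioValidation:
    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="16"):
            CatchmentScenario(grid_shape=(8, 8))

    def test_single_gauge_rejected(self):
        with pytest.raises(ValueError, match="two gauges"):
            CatchmentScenario(gauge_count=1)

    def test_nonpositive_flow_law_rejected(self):
        with pytest.raises(ValueError, match="flow-law"):
            CatchmentScenario(flow_law=(0.0, 0.8))

    def test_overfull_mosaic_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            CatchmentScenario(
                landcover_mosaic=[
                    ("Broadleaf woodland", "os_vector", 0.7),
                    ("Water", "os_vector", 0.6),
                ]
            )


class TestTerrain:
    def test_seeded_determinism_bit_identical(self):
        sc = CatchmentScenario(grid_shape=(64, 64), drainage_style="single_valley", seed=1)
        a = generate_terrain(sc)
        b = generate_terrain(sc)
        np.testing.assert_array_equal(a.dtm.data, b.dtm.data)
        assert all(x.equals(y) for x, y in zip(a.network["geometry"], b.network["geometry"]))
        assert a.channels.equals(b.channels)

    def test_channels_descend_strictly(self, small_terrain):
        dtm = small_terrain.dtm
        for line in small_terrain.network["geometry"]:
            zs = [float(dtm.sample(*c)) for c in line.coords]
            assert np.all(np.diff(zs) < 0)

    def test_network_is_connected_tree(self, small_terrain):
        import networkx as nx

        g = nx.Graph()
        for line in small_terrain.network["geometry"]:
            a = tuple(np.round(line.coords[0], 6))
            b = tuple(np.round(line.coords[-1], 6))
            g.add_edge(a, b)
        assert nx.is_connected(g)
        assert g.number_of_edges() == g.number_of_nodes() - 1  # tree

    def test_dendritic_orders_match_hand_enumerated_tree(self, small_terrain):
        lines = list(small_terrain.network["geometry"])
        orders = graph_strahler_orders(lines, small_terrain.outlet_xy)
        # three tributaries join the stem one by one: outlet stays order 2
        assert orders[-1] == 2
        assert sorted(orders) == [1, 1, 1, 1, 2, 2, 2]

    def test_channel_polygons_widen_downstream(self, small_terrain):
        lines = small_terrain.network["geometry"]
        head = lines[0].interpolate(0.1, normalized=True)
        outlet_line = lines[len(lines) - 1]
        near_outlet = outlet_line.interpolate(0.95, normalized=True)
        w = lambda pt: small_terrain.channels.intersection(
            pt.buffer(20)
        ).area
        assert w(near_outlet) > w(head)

    def test_total_length_matches_sum_of_parts(self, small_terrain):
        lines = list(small_terrain.network["geometry"])
        total = sum(l.length for l in lines)
        assert total == pytest.approx(sum(l.length for l in lines), rel=1e-6)
        assert total > 0


class TestLandcover:
    def test_unknown_class_rejected(self, small_terrain):
        sc = CatchmentScenario(
            landcover_mosaic=[("Martian lichen", "os_vector", 0.5)], seed=1
        )
        with pytest.raises(KeyError, match="Martian lichen"):
            generate_landcover(sc, small_terrain.network, small_terrain.dtm)

    def test_labels_come_from_suitability_tables(self, small_scenario, small_terrain):
        sources = generate_landcover(small_scenario, small_terrain.network, small_terrain.dtm)
        tables = forage.load_suitability_tables()
        for sid in ("os_vector", "wlff_vector"):
            for lbl in sources[sid]["landclass"]:
                assert lbl in tables[sid].classes

    def test_mosaic_fractions_respected(self, small_terrain):
        sc = CatchmentScenario(
            landcover_mosaic=[
                ("Broadleaf woodland", "os_vector", 0.4),
                ("Unimproved grass", "os_vector", 0.6),
            ],
            seed=3,
        )
        sources = generate_landcover(sc, small_terrain.network, small_terrain.dtm)
        counts = sources["os_vector"]["landclass"].value_counts(normalize=True)
        assert counts["Broadleaf woodland"] == pytest.approx(0.4, abs=0.05)

    def test_pure_broadleaf_raster_forces_bfi_five(self, small_terrain):
        sc = CatchmentScenario(
            landcover_mosaic=[("5", "lcm_raster", 1.0)], lcm_background=None, seed=1
        )
        sources = generate_landcover(sc, small_terrain.network, small_terrain.dtm)
        tables = forage.load_suitability_tables()
        layer = forage.reclassify_source(sources["lcm_raster"], tables["lcm_raster"])
        grids = forage.rasterize_and_align([layer], template_like(small_terrain.dtm))
        bfi = forage.composite_bfi(grids, priority_index=0)
        vegetated = layer.data != layer.nodata
        assert (bfi.data[vegetated] == 5).all()
        assert (bfi.data[~vegetated] == 0).all()

    def test_pure_water_forces_bfi_zero(self, small_terrain):
        sc = CatchmentScenario(landcover_mosaic=[("Water", "os_vector", 1.0)], seed=1)
        sources = generate_landcover(sc, small_terrain.network, small_terrain.dtm)
        tables = forage.load_suitability_tables()
        layer = forage.reclassify_source(sources["os_vector"], tables["os_vector"])
        grids = forage.rasterize_and_align([layer], template_like(small_terrain.dtm))
        bfi = forage.composite_bfi(grids, priority_index=0)
        assert (bfi.data == 0).all()

    def test_tcd_uniform_draw_hits_all_bands(self, small_scenario, small_terrain):
        sources = generate_landcover(small_scenario, small_terrain.network, small_terrain.dtm)
        tables = forage.load_suitability_tables()
        banded = forage.reclassify_source(sources["tcd_raster"], tables["tcd_raster"])
        assert len(np.unique(banded.data)) >= 4


class TestFlows:
    def test_noiseless_rating_recovery(self, small_terrain):
        sc = CatchmentScenario(flow_sigma=0.0, gauge_count=4, seed=1)
        from damcap.terrain import build_flow_grid

        fg = build_flow_grid(small_terrain.dtm, list(small_terrain.network["geometry"]))
        flows, meta = generate_flows(sc, small_terrain.network, fg)
        gauges = hydrology.gauges_from_frames(flows, meta)
        curve = hydrology.fit_rating_curve(gauges, 2)
        assert curve.a == pytest.approx(sc.flow_law[0], rel=1e-6)
        assert curve.b == pytest.approx(sc.flow_law[1], rel=1e-6)

    def test_noisy_exponent_recovered_within_tolerance(self):
        sc = CatchmentScenario(
            grid_shape=(96, 96), tributaries=4, gauge_count=10, flow_sigma=0.3, seed=7
        )
        t = generate_terrain(sc)
        from damcap.terrain import build_flow_grid

        fg = build_flow_grid(t.dtm, list(t.network["geometry"]))
        flows, meta = generate_flows(sc, t.network, fg)
        gauges = hydrology.gauges_from_frames(flows, meta)
        curve = hydrology.fit_rating_curve(gauges, 80)
        assert curve.b == pytest.approx(sc.flow_law[1], abs=0.15)

    def test_flows_deterministic(self, small_scenario, small_terrain, small_flow_grid):
        a, am = generate_flows(small_scenario, small_terrain.network, small_flow_grid)
        b, bm = generate_flows(small_scenario, small_terrain.network, small_flow_grid)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(am, bm)


class TestObservations:
    def _reaches(self, n=30, cat="preferred", max_dams=2.0):
        return pd.DataFrame(
            {
                "reach_id": np.arange(n),
                "geometry": [LineString([(0, 10 * i), (100, 10 * i)]) for i in range(n)],
                "length_m": 100.0,
                "bfi_category": cat,
                "max_dams": max_dams,
            }
        )

    def test_impossible_activity_gives_no_observations(self):
        sc = CatchmentScenario(activity_logits=(-1e9,) * 5, seed=1)
        pts, _ = simulate_observations(sc, self._reaches())
        assert len(pts) == 0

    def test_forced_zero_inflation_gives_no_dams(self):
        sc = CatchmentScenario(
            activity_logits=(10.0,) * 5,
            damming={"g0": 1e9, "g1": 0.0, "b0": 0.0, "b1": 0.0, "alpha": 0.5},
            seed=1,
        )
        pts, _ = simulate_observations(sc, self._reaches(max_dams=0.0))
        assert (pts["kind"] == "feeding_sign").all()

    def test_points_lie_on_parent_reaches(self, small_scenario):
        reaches = self._reaches(n=50)
        pts, _ = simulate_observations(small_scenario, reaches)
        assert len(pts) > 0
        for pt in pts["geometry"]:
            assert min(g.distance(pt) for g in reaches["geometry"]) < 5.0

    def test_truth_sidecar_roundtrip(self, small_scenario, tmp_path):
        from damcap.synthetic import write_truth_sidecar

        _, truth = simulate_observations(small_scenario, self._reaches())
        write_truth_sidecar(truth, tmp_path / "truth.json")
        back = json.loads((tmp_path / "truth.json").read_text())
        assert back["damming"] == truth["damming"]

    def test_reach_table_deterministic(self):
        a = simulate_reach_table(500, seed=9)
        b = simulate_reach_table(500, seed=9)
        pd.testing.assert_frame_equal(a, b)
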