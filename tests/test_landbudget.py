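import numpy as np
import pytest
import shapely

from dairyshed import landbudget as lb
from dairyshed import tables
from dairyshed.herd import Diet, FeedItem
from dairyshed.raster import GridSpec, RasterLayer

GRID = GridSpec(pixel_size=1000.0)


def L(vals):
    return RasterLayer(np.asarray(vals, dtype=float), grid=GRID)


SILAGE = {"silage": FeedItem("silage", 0.68, 0.08, crop_yield=1.766, is_cultivated=True)}


def level(y):
    return lb.YieldGapLevel("Ya", {"X": y}, {"X": 0.0})


# ---------------------------------------------------------------- demand
def test_zero_density_zero_demand():
    demand = lb.feed_land_demand(L([[0.0]]), Diet(intakes={"silage": 883.0}), SILAGE, level(1.766))
    assert demand.values[0, 0] == 0.0


def test_demand_hand_arithmetic():
    # 10 head × 883 kg silage at 1.766 t/ha on a 1-km² pixel -> 5.0 ha
    demand = lb.feed_land_demand(L([[10.0]]), Diet(intakes={"silage": 883.0}), SILAGE, level(1.766))
    assert demand.values[0, 0] == pytest.approx(5.0)


def test_doubling_yield_halves_demand():
    d1 = lb.feed_land_demand(L([[10.0]]), Diet(intakes={"silage": 883.0}), SILAGE, level(1.766))
    d2 = lb.feed_land_demand(L([[10.0]]), Diet(intakes={"silage": 883.0}), SILAGE, level(3.532))
    assert d2.values[0, 0] == pytest.approx(d1.values[0, 0] / 2.0)


def test_zero_yield_rejected():
    with pytest.raises(ValueError, match="yield"):
        lb.feed_land_demand(L([[10.0]]), Diet(intakes={"silage": 883.0}), SILAGE, level(0.0))


def test_uncultivated_feeds_add_no_demand():
    feeds = {"pasture": FeedItem("pasture", 0.55, 0.08)}
    demand = lb.feed_land_demand(L([[10.0]]), Diet(intakes={"pasture": 2000.0}), feeds, level(1.0))
    assert demand.values[0, 0] == 0.0


# ---------------------------------------------------------------- deficit polygons
def test_no_deficit_no_polygons():
    mask, polys = lb.land_deficit(L([[1.0, 1.0]]), L([[2.0, 2.0]]))
    assert not mask.any() and polys == []


def test_single_deficit_pixel_is_unit_square():
    mask, polys = lb.land_deficit(L([[3.0, 1.0]]), L([[2.0, 2.0]]))
    assert mask.tolist() == [[True, False]]
    assert len(polys) == 1
    assert polys[0].area == pytest.approx(1000.0 * 1000.0)


def test_diagonal_pixels_join_under_8_connectivity():
    demand = L([[3.0, 0.0], [0.0, 3.0]])
    avail = L([[1.0, 1.0], [1.0, 1.0]])
    _, polys = lb.land_deficit(demand, avail)
    assert len(polys) == 1


# ---------------------------------------------------------------- buffering
def test_buffer_empty_set():
    assert lb.buffer_deficit([]) == []


def test_buffer_zero_radius_identity():
    sq = shapely.box(0, 0, 1000, 1000)
    assert lb.buffer_deficit([sq], 0.0)[0].equals(sq)


def test_buffer_area_minkowski_closed_form():
    # 1 km² square + 5 km buffer: 1 + 4·(1·5) + π·25 km² ≈ 99.54 km²
    sq = shapely.box(0, 0, 1000, 1000)
    buffered = lb.buffer_deficit([sq], 5000.0)[0]
    expected_km2 = 1 + 4 * 5 + np.pi * 25
    assert buffered.area / 1e6 == pytest.approx(expected_km2, rel=1e-3)


def test_buffer_requires_projected_crs():
    with pytest.raises(ValueError, match="projected"):
        lb.buffer_deficit([shapely.box(0, 0, 1, 1)], 5000.0, crs="EPSG:4326")


# ---------------------------------------------------------------- scenario forest loss
def test_scenario_forest_loss_limits():
    loss = L([[1.0, 2.0], [3.0, 4.0]])
    base = loss.total_co2eq_mg()
    out = lb.scenario_forest_loss(loss, [])
    assert out["retained_mg_co2eq"] == 0.0
    assert out["mitigated_mg_co2eq"] == pytest.approx(base)
    out = lb.scenario_forest_loss(loss, [shapely.box(-1e9, -1e9, 1e9, 1e9)])
    assert out["mitigated_mg_co2eq"] == pytest.approx(0.0)
    assert out["retained_mg_co2eq"] == pytest.approx(base)


def test_scenario_forest_loss_toy_enumeration():
    vals = np.arange(1.0, 10.0).reshape(3, 3)
    loss = L(vals)
    # square covering the NW 2x2 block of pixel centres
    poly = shapely.box(0, -2000, 2000, 0)
    out = lb.scenario_forest_loss(loss, [poly])
    hand = (1 + 2 + 4 + 5) * 100.0 * (44 / 12) / 1000.0
    assert out["retained_mg_co2eq"] == pytest.approx(hand)


# ---------------------------------------------------------------- LUC and footprint
def test_luc_emissions_reproduce_worst_case_totals():
    assert lb.luc_emissions(0.0, 112.7)[0] == 0.0
    mt_high, sd_high = lb.worst_case_deforestation(1_045_921.0)
    assert mt_high == pytest.approx(117.9, abs=0.1)
    assert round(mt_high) == 118
    mt_med, sd_med = lb.worst_case_deforestation(501_800.0)
    assert mt_med == pytest.approx(56.6, abs=0.1)
    assert round(mt_med) == 57
    assert round(sd_med) == 2 and round(sd_high) == 4


def test_concentrate_demand_from_cow_populations():
    pops = tables.population_table().set_index("lps")["productive_dairy_cows"]
    t450 = lb.concentrate_demand(pops, 450.0)
    assert round(t450["MRA"]) == 66_484
    assert round(t450["MRT"]) == 659_702
    assert round(t450["total"]) == 807_863
    t900 = lb.concentrate_demand(pops, 900.0)
    assert round(t900["total"]) == 1_615_726


def test_concentrate_footprint_reproduces_reported_areas():
    fp = lb.concentrate_footprint(807_863.0).set_index("ingredient")
    assert round(fp.loc["rice_bran", "scenario_ha"]) == 75_059
    assert round(fp.loc["wheat_grain", "baseline_ha"]) == 8_790
    assert round(fp.loc["total", "scenario_ha"]) == pytest.approx(501_800, abs=1)
    fp_high = lb.concentrate_footprint(1_615_726.0).set_index("ingredient")
    assert round(fp_high.loc["total", "scenario_ha"]) == pytest.approx(1_045_921, abs=1)


def test_footprint_conservation():
    fp = lb.concentrate_footprint(807_863.0)
    parts = fp[fp.ingredient != "total"]
    total = fp[fp.ingredient == "total"].iloc[0]
    assert parts.scenario_t.sum() == pytest.approx(total.scenario_t)
    assert parts.scenario_ha.sum() == pytest.approx(total.scenario_ha, abs=1.0)
    assert total.scenario_t == pytest.approx(807_863.0)


def test_footprint_rejects_bad_fractions():
    comp = tables.concentrate_composition()
    comp.loc[0, "fraction"] = 0.5
    with pytest.raises(ValueError, match="sum to 1"):
        lb.concentrate_footprint(1000.0, composition=comp)


# ---------------------------------------------------------------- fertilizer requirement
def test_applied_nitrogen_inverse_nue():
    assert lb.applied_nitrogen(35.7, 0.33) == pytest.approx(108.18, abs=0.01)
    assert lb.applied_nitrogen(50.0, 1.0) == 50.0
    assert lb.applied_nitrogen(0.0, 0.33) == 0.0
    with pytest.raises(ValueError):
        lb.applied_nitrogen(10.0, 0.0)


def test_default_yield_levels_monotone():
    levels = lb.default_yield_gap_levels()
    ys = [levels[k].yield_for("MRA") for k in ("Ya", "Yw50", "Yw80")]
    ns = [levels[k].n_input_for("MRA") for k in ("Ya", "Yw50", "Yw80")]
    assert ys == sorted(ys) and ns == sorted(ns)
    assert ns[0] == 0.0  # actual yields need no extra fertilizer


def test_fertilizer_requirement_manure_share_raises_total():
    levels = lb.default_yield_gap_levels()
    all_fert = lb.fertilizer_n_requirement(levels["Yw80"], "MRA", 1.0)
    half = lb.fertilizer_n_requirement(levels["Yw80"], "MRA", 0.5)
    assert half > all_fert  # manure NUE is lower, so more total N is applied


# ---------------------------------------------------------------- budget chain
def test_compute_land_budget_luc_capped_by_availability():
    demand = L([[5.0, 50.0]])
    avail = L([[10.0, 20.0]])
    budget = lb.compute_land_budget(demand, avail)
    np.testing.assert_allclose(budget.luc_area.values, [[5.0, 20.0]])
    assert budget.deficit_mask.tolist() == [[False, True]]
    assert budget.deficit_area_ha == pytest.approx(100.0)
    # buffered polygons contain the unbuffered ones
    for p, b in zip(budget.deficit_polygons, budget.buffered_polygons):
        assert b.contains(p)
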