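"""Feed-land demand, land deficits, and the concentrate land footprint.

Per pixel, the cropland needed to grow a scenario's cultivated feeds
(Napier grass and silage maize) is compared with the grazing land
available for conversion; pixels where demand exceeds availability are
land-deficit pixels. Deficit pixels are dissolved into 8-connected
polygons and buffered by the farm-neighbourhood radius (5 km): forest
pixels whose centres fall inside a buffered deficit polygon keep their
grazing-attributed C loss in that scenario, the rest counts as mitigated.

Closing the maize yield gap (actual yield Ya → 50% or 80% of the
water-limited potential Yw) shrinks demand at the cost of fertilizer N,
whose application rate is the extra crop N uptake divided by the nitrogen
use efficiency. The concentrate land footprint is a separate, aspatial
account based on national ingredient yields; it is never added to the
spatial budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from . import tables
from .herd import Diet, FeedItem
from .raster import RasterLayer, crs_is_projected

CO2_PER_C = 44.0 / 12.0


# ---------------------------------------------------------------------------
# Yield-gap levels
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class YieldGapLevel:
    """A maize yield-gap closure level with its fertilizer requirement.

    ``maize_yield`` and ``n_input_required`` (additional fertilizer N to
    reach the level, kg N/ha) are per-LPS mappings; the default levels use
    one value across systems.
    """

    label: str
    maize_yield: Mapping[str, float]
    n_input_required: Mapping[str, float]
    nue_fertilizer: float = tables.NUE_FERTILIZER
    nue_manure: float = tables.NUE_MANURE

    def yield_for(self, lps: str | None) -> float:
        if lps is not None and lps in self.maize_yield:
            return self.maize_yield[lps]
        return float(np.mean(list(self.maize_yield.values())))

    def n_input_for(self, lps: str | None) -> float:
        if lps is not None and lps in self.n_input_required:
            return self.n_input_required[lps]
        return float(np.mean(list(self.n_input_required.values())))


def applied_nitrogen(uptake_kg_ha: float, nue: float) -> float:
    """Fertilizer N to apply so the crop takes up ``uptake_kg_ha`` at the given NUE."""
    if not 0 < nue <= 1:
        raise ValueError("NUE must be in (0, 1]")
    if uptake_kg_ha < 0:
        raise ValueError("N uptake must be >= 0")
    return uptake_kg_ha / nue


def default_yield_gap_levels(
    ya: float = tables.MAIZE_YA,
    yw: float = tables.MAIZE_YW,
    uptake_per_t: float = tables.MAIZE_N_UPTAKE_PER_T,
    lps_classes=tables.LPS_CLASSES,
) -> dict[str, YieldGapLevel]:
    """The three levels Ya / Yw50 / Yw80 with default maize parameters."""
    levels = {}
    for label, y in (("Ya", ya), ("Yw50", 0.5 * yw), ("Yw80", 0.8 * yw)):
        extra_uptake = max(y - ya, 0.0) * uptake_per_t
        n_applied = applied_nitrogen(extra_uptake, tables.NUE_FERTILIZER)
        levels[label] = YieldGapLevel(
            label=label,
            maize_yield={lps: y for lps in lps_classes},
            n_input_required={lps: n_applied for lps in lps_classes},
        )
    ys = [levels[k].yield_for(None) for k in ("Ya", "Yw50", "Yw80")]
    if not (ys[0] <= ys[1] <= ys[2]):
        raise ValueError("yield levels must be non-decreasing Ya <= Yw50 <= Yw80")
    return levels


def fertilizer_n_requirement(
    level: YieldGapLevel,
    lps: str,
    fraction_fertilizer: float = 1.0,
) -> float:
    """Applied N (kg/ha) for a yield level, split between fertilizer and manure.

    The stored per-level requirement assumes all N comes from fertilizer at
    its NUE; diverting a share to manure re-prices that share at the manure
    NUE (manure is less efficient, so the total applied N rises).
    """
    if not 0 <= fraction_fertilizer <= 1:
        raise ValueError("fraction_fertilizer must be in [0,1]")
    base = level.n_input_for(lps)  # all-fertilizer requirement
    uptake = base * level.nue_fertilizer
    return applied_nitrogen(uptake * fraction_fertilizer, level.nue_fertilizer) + (
        applied_nitrogen(uptake * (1 - fraction_fertilizer), level.nue_manure)
        if fraction_fertilizer < 1
        else 0.0
    )


# ---------------------------------------------------------------------------
# Spatial demand and deficit
# ---------------------------------------------------------------------------
def _cultivated_demand_ha_per_head(
    diet: Diet, feeds: Mapping[str, FeedItem], yield_level: YieldGapLevel, lps: str | None
) -> float:
    """Cropland (ha) to feed one cow for a year under the diet."""
    total = 0.0
    for name, kg in diet.intakes.items():
        feed = feeds[name]
        if not feed.is_cultivated or kg == 0:
            continue
        y = yield_level.yield_for(lps) if name == "silage" else feed.crop_yield
        if y is None or y <= 0:
            raise ValueError(f"cultivated feed {name} has non-positive yield")
        total += kg / 1000.0 / y
    return total


def feed_land_demand(
    cattle_density: RasterLayer,
    diets: Diet | Mapping[str, Diet],
    feeds: Mapping[str, FeedItem],
    yield_level: YieldGapLevel,
    lps_class: RasterLayer | None = None,
    lps_names: tuple[str, ...] = tuple(tables.LPS_CLASSES),
    head_scale: np.ndarray | float = 1.0,
) -> RasterLayer:
    """Per-pixel cropland demand (ha) to grow the scenario's cultivated feeds.

    ``cattle_density`` is in head/km²; ``head_scale`` rescales head counts
    (e.g. by the county dairy proportion or the productive-cow share).
    With a mapping of per-LPS diets an ``lps_class`` raster selects the
    diet per pixel.
    """
    km2 = cattle_density.grid.pixel_area_ha / 100.0
    heads = np.where(cattle_density.valid_mask, cattle_density.values, 0.0) * km2 * head_scale
    demand = np.zeros(cattle_density.shape)
    if isinstance(diets, Diet):
        demand = heads * _cultivated_demand_ha_per_head(diets, feeds, yield_level, None)
    else:
        if lps_class is None:
            raise ValueError("per-LPS diets require an lps_class raster")
        codes = lps_class.values.astype(int)
        for i, lps in enumerate(lps_names):
            if lps not in diets:
                continue
            per_head = _cultivated_demand_ha_per_head(diets[lps], feeds, yield_level, lps)
            demand += np.where(codes == i, heads * per_head, 0.0)
    return cattle_density.with_values(demand, units="ha")


def land_deficit(
    demand: RasterLayer, available: RasterLayer
) -> tuple[np.ndarray, list[shapely.Geometry]]:
    """Deficit mask (demand > available) and dissolved 8-connected polygons."""
    demand.require_same_grid(available, "demand and availability")
    mask = (demand.values > available.values) & demand.valid_mask & available.valid_mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    polys: list[shapely.Geometry] = []
    if n == 0:
        return mask, polys
    ps = demand.grid.pixel_size
    x0, y0 = demand.grid.x_origin, demand.grid.y_origin
    for lbl in range(1, n + 1):
        rows, cols = np.where(labels == lbl)
        boxes = shapely.box(
            x0 + cols * ps, y0 - (rows + 1) * ps, x0 + (cols + 1) * ps, y0 - rows * ps
        )
        polys.append(shapely.union_all(boxes))
    return mask, polys


def buffer_deficit(
    polygons: list[shapely.Geometry],
    radius_m: float = 5000.0,
    crs: str = "EPSG:32637",
) -> list[shapely.Geometry]:
    """Euclidean buffer of deficit polygons in a projected CRS."""
    if not crs_is_projected(crs):
        raise ValueError(
            f"buffering requires projected coordinates, got geographic CRS {crs!r}"
        )
    if radius_m == 0:
        return list(polygons)
    return [shapely.buffer(p, radius_m, quad_segs=32) for p in polygons]


def scenario_forest_loss(
    c_loss_cattle: RasterLayer, buffered_polygons: list[shapely.Geometry]
) -> dict[str, float]:
    """Retained vs mitigated grazing-attributed forest loss, Mg CO2eq yr⁻¹.

    Forest pixels whose centres intersect a buffered land-deficit polygon
    retain their loss (feed shortfall still drives forest grazing there);
    everything else is mitigated relative to the baseline total.
    """
    baseline = c_loss_cattle.total_co2eq_mg()
    valid = c_loss_cattle.valid_mask
    if not buffered_polygons or not valid.any():
        return {"retained_mg_co2eq": 0.0, "mitigated_mg_co2eq": baseline}
    xs, ys = c_loss_cattle.grid.pixel_centers(c_loss_cattle.shape)
    union = shapely.union_all(buffered_polygons)
    inside = shapely.intersects_xy(union, xs[valid], ys[valid])
    scale = c_loss_cattle.grid.pixel_area_ha * CO2_PER_C / 1000.0
    retained = float(c_loss_cattle.values[valid][inside].sum() * scale)
    return {"retained_mg_co2eq": retained, "mitigated_mg_co2eq": baseline - retained}


def luc_emissions(
    converted_area_ha: float, luc_ef: float, ef_sd: float = 0.0
) -> tuple[float, float]:
    """Land-use-change emissions (Mg CO2eq) and SD from area × factor."""
    if converted_area_ha < 0:
        raise ValueError("converted area must be >= 0")
    return converted_area_ha * luc_ef, converted_area_ha * ef_sd


@dataclass
class LandBudget:
    """Per-scenario spatial land budget."""

    demand: RasterLayer
    available: RasterLayer
    deficit_mask: np.ndarray
    deficit_polygons: list = field(default_factory=list)
    buffered_polygons: list = field(default_factory=list)
    luc_area: RasterLayer | None = None  # ha actually converted per pixel

    @property
    def deficit_area_ha(self) -> float:
        return float(self.deficit_mask.sum() * self.demand.grid.pixel_area_ha)

    @property
    def total_converted_ha(self) -> float:
        if self.luc_area is None:
            return 0.0
        return float(self.luc_area.values[self.luc_area.valid_mask].sum())


def compute_land_budget(
    demand: RasterLayer,
    available: RasterLayer,
    buffer_radius_m: float = 5000.0,
) -> LandBudget:
    """Full land-budget chain: deficit mask → polygons → 5-km buffers → LUC area.

    The grazing land actually converted per pixel is min(demand,
    available): only existing grazing land is convertible to cropland.
    """
    mask, polys = land_deficit(demand, available)
    buffered = buffer_deficit(polys, buffer_radius_m, crs=demand.grid.crs)
    converted = np.minimum(demand.values, available.values)
    converted[~(demand.valid_mask & available.valid_mask)] = 0.0
    return LandBudget(
        demand=demand,
        available=available,
        deficit_mask=mask,
        deficit_polygons=polys,
        buffered_polygons=buffered,
        luc_area=demand.with_values(converted, units="ha"),
    )


# ---------------------------------------------------------------------------
# Concentrate demand and land footprint (aspatial, national yields)
# ---------------------------------------------------------------------------
def concentrate_demand(
    productive_cows: pd.Series | Mapping[str, float], annual_kg_per_head: float
) -> pd.Series:
    """Concentrate tonnes per LPS plus a ``total`` entry."""
    s = pd.Series(productive_cows, dtype=float)
    if (s < 0).any():
        raise ValueError("cow counts must be >= 0")
    tonnes = s * annual_kg_per_head / 1000.0
    tonnes["total"] = tonnes.sum()
    return tonnes


def concentrate_footprint(
    total_tonnes: float,
    composition: pd.DataFrame | None = None,
    baseline_tonnes: float = tables.BASELINE_CONCENTRATE_T,
) -> pd.DataFrame:
    """Land footprint of concentrate production at national ingredient yields.

    Per ingredient: tonnes = fraction × total; the area is the land needed
    for that tonnage minus the land already allocated in the baseline.
    Returns a tidy frame with a ``total`` row appended.
    """
    comp = tables.concentrate_composition() if composition is None else composition
    fractions = comp["fraction"].to_numpy(dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"ingredient fractions must sum to 1, got {fractions.sum()}")
    yields = comp["yield_t_ha"].to_numpy(dtype=float)
    if (yields <= 0).any():
        raise ValueError("ingredient yields must be positive")

    baseline_t = fractions * baseline_tonnes
    baseline_ha = baseline_t / yields
    scenario_t = fractions * total_tonnes
    scenario_ha = scenario_t / yields - baseline_ha

    out = pd.DataFrame(
        {
            "ingredient": comp["ingredient"],
            "fraction": fractions,
            "yield_t_ha": yields,
            "baseline_t": baseline_t,
            "baseline_ha": baseline_ha,
            "scenario_t": scenario_t,
            "scenario_ha": scenario_ha,
        }
    )
    total = pd.DataFrame(
        {
            "ingredient": ["total"],
            "fraction": [1.0],
            "yield_t_ha": [np.nan],
            "baseline_t": [baseline_t.sum()],
            "baseline_ha": [baseline_ha.sum()],
            "scenario_t": [scenario_t.sum()],
            "scenario_ha": [scenario_ha.sum()],
        }
    )
    return pd.concat([out, total], ignore_index=True)


def worst_case_deforestation(
    footprint_area_ha: float,
    ef: float = tables.FOREST_TO_CROPLAND_EF,
    ef_sd: float = tables.FOREST_TO_CROPLAND_EF_SD,
) -> tuple[float, float]:
    """Worst-case forest→cropland emissions (Mt CO2eq) for a footprint area."""
    mg, sd = luc_emissions(footprint_area_ha, ef, ef_sd)
    return mg / 1e6, sd / 1e6
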