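"""Scenario orchestration: baseline and feed-improvement runs.

Three feed-improvement scenarios are compared against a baseline diet:

* **FoCo** — forage quality: more Napier grass plus 3 kg/day concentrate
  (medium intensification, 25% of baseline DM replaced); no maize silage,
  so only actual maize yields (Ya) apply.
* **FeCo** — feed conservation: maize silage plus 3 kg/day concentrate
  (medium intensification), at maize yield-gap levels Ya/Yw50/Yw80.
* **FoFeCo** — Napier, silage and 6 kg/day concentrate (high
  intensification, 50% replaced), at all three yield levels.

A run chains the stages: per-LPS herd accounting (milk from the
calibrated per-system yields, Tier-2 emission kernels), the spatial land
budget for the *additional* cropland the scenario requires relative to
the baseline, and the forest stage, where buffered land-deficit polygons
decide how much grazing-attributed forest C loss is retained. Forest C
change enters the combined AFOLU total as a signed term (gain credited,
retained loss debited); the concentrate worst-case deforestation is
reported separately and never added to the combined total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import herd, landbudget, tables
from .attribution import AttributionResult, attribute_grazing_loss, natural_forest_mask
from .herd import Diet, EmissionFactors
from .landbudget import LandBudget, YieldGapLevel
from .raster import RasterLayer
from .synthetic import Landscape

#: share of the dairy herd that is productive (milking); the study-area
#: population table uses exactly 0.6
PRODUCTIVE_SHARE = 0.6

_SCENARIO_DEFS = {
    "baseline": dict(intensification=None, replacement_fraction=0.0, concentrate_kg_day=0.0),
    "FoCo": dict(intensification="medium", replacement_fraction=0.25, concentrate_kg_day=3.0),
    "FeCo": dict(intensification="medium", replacement_fraction=0.25, concentrate_kg_day=3.0),
    "FoFeCo": dict(intensification="high", replacement_fraction=0.50, concentrate_kg_day=6.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A feed scenario × maize yield-gap level."""

    name: str
    yield_level: str = "Ya"
    intensification: str | None = None
    replacement_fraction: float = 0.0
    concentrate_kg_day: float = 0.0

    def __post_init__(self):
        if self.name not in _SCENARIO_DEFS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.yield_level not in tables.YIELD_LEVELS:
            raise ValueError(f"unknown yield level {self.yield_level!r}")
        if self.name in ("baseline", "FoCo") and self.yield_level != "Ya":
            raise ValueError(f"{self.name} is defined only at actual maize yields (Ya)")

    @classmethod
    def create(cls, name: str, yield_level: str = "Ya") -> "ScenarioSpec":
        if name not in _SCENARIO_DEFS:
            raise ValueError(f"unknown scenario {name!r}")
        return cls(name=name, yield_level=yield_level, **_SCENARIO_DEFS[name])

    @property
    def key(self) -> str:
        return self.name if self.name in ("baseline", "FoCo") else f"{self.name}-{self.yield_level}"


def all_scenario_specs() -> list[ScenarioSpec]:
    specs = [ScenarioSpec.create("baseline"), ScenarioSpec.create("FoCo")]
    for name in ("FeCo", "FoFeCo"):
        specs += [ScenarioSpec.create(name, yl) for yl in tables.YIELD_LEVELS]
    return specs


# ---------------------------------------------------------------------------
# Diet construction from the per-LPS table
# ---------------------------------------------------------------------------
def diets_for(spec: ScenarioSpec, diet_df: pd.DataFrame | None = None) -> dict[str, Diet]:
    """Per-LPS diets for a scenario from the built-in diet table."""
    df = tables.diet_table() if diet_df is None else diet_df
    rows = df[(df.scenario == spec.name)]
    out: dict[str, Diet] = {}
    for lps in df.lps.unique():
        sub = rows[rows.lps == lps]
        if sub.empty:
            raise KeyError(f"no diet row for LPS {lps!r} under scenario {spec.name!r}")
        r = sub.iloc[0]
        out[lps] = Diet(
            intakes={c: float(r[c]) for c in tables.FEED_COLUMNS},
            lps=lps,
            scenario=spec.name,
            concentrate_kg_day=spec.concentrate_kg_day,
        )
    return out


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------
@dataclass
class ScenarioResult:
    """All outputs of one scenario × yield-level run.

    Emissions are study-area aggregates in Mg CO2eq yr⁻¹; milk in
    kg FPCM yr⁻¹; intensities in kg CO2eq per kg FPCM.
    """

    spec: ScenarioSpec
    milk_per_head: pd.Series  # kg FPCM head-1 yr-1 per LPS
    milk_by_lps: pd.Series  # kg FPCM yr-1
    emissions_by_category: dict[str, float]  # Mg CO2eq yr-1
    forest_retained_mg: float
    forest_mitigated_mg: float
    forest_gain_mg: float
    concentrate_t: pd.Series
    land: LandBudget | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def milk_total(self) -> float:
        return float(self.milk_by_lps.sum())

    @property
    def agricultural_total_mg(self) -> float:
        return float(sum(self.emissions_by_category.values()))

    @property
    def forest_c_change_mg(self) -> float:
        """Forest C gain minus retained grazing loss (positive = net sink)."""
        return self.forest_gain_mg - self.forest_retained_mg

    @property
    def combined_total_mg(self) -> float:
        """Agricultural emissions minus the forest C change credit."""
        return self.agricultural_total_mg - self.forest_c_change_mg

    @property
    def intensity(self) -> float:
        return herd.emission_intensity(self.agricultural_total_mg * 1000.0, self.milk_total)

    @property
    def intensity_with_forest(self) -> float:
        return herd.emission_intensity(self.combined_total_mg * 1000.0, self.milk_total)


# ---------------------------------------------------------------------------
# Main run
# ---------------------------------------------------------------------------
def run_scenario(
    spec: ScenarioSpec,
    landscape: Landscape,
    attribution_result: AttributionResult | None = None,
    populations: pd.Series | None = None,
    factors: EmissionFactors | None = None,
    feeds: Mapping[str, herd.FeedItem] | None = None,
    diet_df: pd.DataFrame | None = None,
    yield_levels: Mapping[str, YieldGapLevel] | None = None,
    calibration: Mapping | None = None,
    amortization_years: float = 20.0,
    buffer_radius_m: float = 5000.0,
) -> ScenarioResult:
    """Run one scenario end to end on a landscape.

    ``populations`` are dairy cows per LPS (defaults to the landscape's
    own cattle layer); the productive share of them is milked and fed the
    scenario concentrate. Land-use-change applies to the additional
    cropland relative to the baseline diet and is amortised over
    ``amortization_years``.
    """
    factors = factors or EmissionFactors()
    feeds = feeds or herd.default_feeds()
    yield_levels = yield_levels or landbudget.default_yield_gap_levels()
    calibration = (
        herd.calibration_from_diet_table(diet_df) if calibration is None else calibration
    )
    if populations is None:
        populations = landscape.cow_population_by_lps()
    productive = populations * PRODUCTIVE_SHARE
    level = yield_levels[spec.yield_level]

    if attribution_result is None:
        attribution_result = attribute_grazing_loss(
            landscape.net_c_loss,
            landscape.net_c_gain,
            landscape.forest_mask,
            landscape.plantation_mask,
            landscape.burn_mask,
            landscape.nrb,
            landscape.counties,
        )
    loss_layer = attribution_result.c_loss_cattle
    gain_mg = _forest_gain_total(landscape)

    # --- manure system split: reduced grazing shifts manure to heaps
    split = dict(factors.manure_split)
    if spec.name in ("FoCo", "FoFeCo"):
        shift = min(0.3, split.get("pasture", 0.0))
        split["pasture"] = split.get("pasture", 0.0) - shift
        split["heap"] = split.get("heap", 0.0) + shift

    # --- herd stage, per LPS
    diets = diets_for(spec, diet_df)
    base_diets = diets_for(ScenarioSpec.create("baseline"), diet_df)
    milk_head, milk_lps = {}, {}
    percow: dict[str, herd.EmissionBreakdown] = {}
    for lps, diet in diets.items():
        milk = herd.lifetime_milk(diet, feeds, calibration=calibration)
        n_fert = _fertilizer_n_per_head(diet, feeds, level, lps)
        percow[lps] = herd.cow_emissions(
            diet, feeds, factors, milk, n_fertilizer=n_fert, system_split=split
        )
        milk_head[lps] = milk
        milk_lps[lps] = milk * productive.get(lps, 0.0)
    milk_head = pd.Series(milk_head)
    milk_lps = pd.Series(milk_lps)

    # aggregate per-head categories to Mg CO2eq yr-1 over productive cows
    emissions = {c: 0.0 for c in herd.EmissionBreakdown.CATEGORIES}
    for lps, br in percow.items():
        heads = productive.get(lps, 0.0)
        for c, v in br.as_dict().items():
            emissions[c] += v * heads / 1000.0

    # --- land stage: additional cropland demand relative to baseline
    dairy_field = landscape.dairy_proportion_field()
    demand = landbudget.feed_land_demand(
        landscape.cattle_density,
        diets,
        feeds,
        level,
        lps_class=landscape.lps_class,
        lps_names=landscape.config.lps_classes,
        head_scale=dairy_field * PRODUCTIVE_SHARE,
    )
    base_demand = landbudget.feed_land_demand(
        landscape.cattle_density,
        base_diets,
        feeds,
        yield_levels["Ya"],
        lps_class=landscape.lps_class,
        lps_names=landscape.config.lps_classes,
        head_scale=dairy_field * PRODUCTIVE_SHARE,
    )
    extra = demand.with_values(np.maximum(demand.values - base_demand.values, 0.0))
    budget = landbudget.compute_land_budget(extra, landscape.grazing_land, buffer_radius_m)
    luc_mg, _ = landbudget.luc_emissions(
        budget.total_converted_ha, factors.luc_ef_grass_to_crop.mean
    )
    emissions["luc_co2"] += luc_mg / amortization_years

    # --- forest stage
    if spec.name == "baseline":
        retained = loss_layer.total_co2eq_mg()
        mitigated = 0.0
    else:
        fl = landbudget.scenario_forest_loss(loss_layer, budget.buffered_polygons)
        retained, mitigated = fl["retained_mg_co2eq"], fl["mitigated_mg_co2eq"]

    conc = landbudget.concentrate_demand(
        productive, annual_kg_per_head=_concentrate_kg(diets)
    )

    return ScenarioResult(
        spec=spec,
        milk_per_head=milk_head,
        milk_by_lps=milk_lps,
        emissions_by_category=emissions,
        forest_retained_mg=retained,
        forest_mitigated_mg=mitigated,
        forest_gain_mg=gain_mg,
        concentrate_t=conc,
        land=budget,
        provenance={
            "scenario": spec.key,
            "seed": landscape.config.seed,
            "amortization_years": amortization_years,
            "buffer_radius_m": buffer_radius_m,
        },
    )


def _forest_gain_total(landscape: Landscape) -> float:
    nat = natural_forest_mask(landscape.forest_mask, landscape.plantation_mask)
    gain = landscape.net_c_gain
    m = nat & gain.valid_mask
    return float(
        gain.values[m].sum() * gain.grid.pixel_area_ha * (44.0 / 12.0) / 1000.0
    )


def _fertilizer_n_per_head(diet, feeds, level: YieldGapLevel, lps: str) -> float:
    """kg fertilizer N per cow-year: extra N rate × silage area per head."""
    silage_kg = sum(
        kg for n, kg in diet.intakes.items() if n == "silage" and feeds[n].is_cultivated
    )
    if silage_kg == 0:
        return 0.0
    area_ha = silage_kg / 1000.0 / level.yield_for(lps)
    return level.n_input_for(lps) * area_ha


def _concentrate_kg(diets: Mapping[str, Diet]) -> float:
    vals = {d.intakes.get("concentrate", 0.0) for d in diets.values()}
    return float(np.mean(list(vals)))


# ---------------------------------------------------------------------------
# Aggregation and reporting
# ---------------------------------------------------------------------------
def aggregate_study_area(
    intensities: pd.Series, milk_by_lps: pd.Series
) -> float:
    """Production-weighted mean emission intensity across LPS."""
    if (milk_by_lps < 0).any():
        raise ValueError("milk totals must be >= 0")
    w = milk_by_lps.loc[intensities.index]
    return float((intensities * w).sum() / w.sum())


def table_milk_and_intensity(
    scenario: str, yield_level: str = "Ya", populations: pd.DataFrame | None = None
) -> dict[str, float]:
    """Study-area milk total and intensity from the per-LPS fixture table.

    Productive cows × per-head yields give total milk; the aggregate
    intensity is the milk-production-weighted mean of per-LPS intensities.
    """
    pops = tables.population_table() if populations is None else populations
    df = tables.diet_table()
    rows = df[(df.scenario == scenario) & (df.yield_level == yield_level)]
    if rows.empty:
        raise KeyError(f"no fixture rows for {scenario}/{yield_level}")
    merged = rows.merge(pops, on="lps")
    milk = merged.productive_dairy_cows * merged.milk_fpcm
    intensity = float((merged.intensity * milk).sum() / milk.sum())
    return {"milk_total": float(milk.sum()), "intensity": intensity}


def mitigation_report(results: list[ScenarioResult]) -> pd.DataFrame:
    """Comparison table of every scenario against the baseline.

    Emits percentage deltas with the baseline as denominator: agricultural
    emissions, combined (forest-credited) emissions, intensity (both the
    aggregate-ratio convention and the mean per-LPS pairing convention),
    milk increase, and the forest loss mitigated in Mg CO2eq yr⁻¹.
    """
    base = next((r for r in results if r.spec.name == "baseline"), None)
    if base is None:
        raise ValueError("mitigation report requires a baseline result")
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.spec.key,
                "milk_total_kg": r.milk_total,
                "milk_increase_pct": 100.0 * (r.milk_total / base.milk_total - 1.0),
                "agricultural_mg": r.agricultural_total_mg,
                "d_agricultural_pct": 100.0
                * (r.agricultural_total_mg / base.agricultural_total_mg - 1.0),
                "combined_mg": r.combined_total_mg,
                "d_combined_pct": 100.0 * (r.combined_total_mg / base.combined_total_mg - 1.0),
                "forest_retained_mg": r.forest_retained_mg,
                "forest_mitigated_mg": r.forest_mitigated_mg,
                "intensity": r.intensity,
                "d_intensity_pct": 100.0 * (r.intensity / base.intensity - 1.0),
                "intensity_with_forest": r.intensity_with_forest,
            }
        )
    return pd.DataFrame(rows)
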