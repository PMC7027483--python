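"""Tier-2 dairy-cow emission accounting and an energy-balance milk model.

The emission kernels follow the IPCC Tier-2 inventory forms: enteric CH4
as a fixed fraction (Ym) of gross energy intake, manure CH4 from volatile
solids with system-specific methane conversion factors, and N2O from
excreted and fertilizer nitrogen through direct and indirect
(volatilisation, leaching) pathways. Milk output comes from an annualised
energy-balance surrogate of a lifetime dairy-cow simulation: intake energy
is partitioned into maintenance, pregnancy and lactation, with a crude
protein ceiling; a calibration table of observed per-system yields can
override the surrogate so that downstream accounting runs on measured
yields.

Uncertainty is propagated one parameter at a time with Latin hypercube
sampling; per-parameter SD contributions are combined in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import tables

ENERGY_PER_KG_CH4 = 55.65  # MJ per kg CH4
CH4_DENSITY = 0.67  # kg CH4 per m3
N_TO_N2O = 44.0 / 28.0
CP_TO_N = 1.0 / 6.25


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Param:
    """An uncertain scalar carried as a (min, mean, max) range."""

    mean: float
    min: float | None = None
    max: float | None = None

    def __post_init__(self):
        lo = self.mean if self.min is None else self.min
        hi = self.mean if self.max is None else self.max
        object.__setattr__(self, "min", lo)
        object.__setattr__(self, "max", hi)
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"require min <= mean <= max, got {self}")

    @property
    def degenerate(self) -> bool:
        return self.min == self.max


@dataclass(frozen=True)
class FeedItem:
    name: str
    dm_digestibility: float
    crude_protein: float
    gross_energy_density: float = 18.45  # MJ per kg DM
    crop_yield: float | None = None  # t DM per ha, cultivated feeds only
    is_concentrate: bool = False
    is_cultivated: bool = False

    def __post_init__(self):
        if not 0 <= self.dm_digestibility <= 1:
            raise ValueError(f"digestibility outside [0,1] for {self.name}")
        if not 0 <= self.crude_protein <= 1:
            raise ValueError(f"crude protein outside [0,1] for {self.name}")
        if self.is_cultivated and (self.crop_yield is None or self.crop_yield <= 0):
            raise ValueError(f"cultivated feed {self.name} needs a positive crop yield")


def default_feeds() -> dict[str, FeedItem]:
    """Feed registry built from the package's default quality table."""
    out = {}
    for row in tables.feed_table().itertuples():
        out[row.name] = FeedItem(
            name=row.name,
            dm_digestibility=row.dm_digestibility,
            crude_protein=row.crude_protein,
            gross_energy_density=row.gross_energy_density,
            crop_yield=None if pd.isna(row.crop_yield) else float(row.crop_yield),
            is_concentrate=bool(row.is_concentrate),
            is_cultivated=bool(row.is_cultivated),
        )
    return out


@dataclass
class Diet:
    """Annual dry-matter intake per feed for one cow (kg DM head-1 yr-1)."""

    intakes: dict[str, float]
    lps: str = ""
    scenario: str = ""
    concentrate_kg_day: float = 0.0
    lactation_feed_days: int = 150

    def __post_init__(self):
        for name, kg in self.intakes.items():
            if kg < 0:
                raise ValueError(f"negative intake for {name}")

    @property
    def total_dmi(self) -> float:
        return float(sum(self.intakes.values()))


@dataclass
class CowParams:
    """Lifetime and physiology of the simulated dairy cow."""

    lifetime_years: float = 13.0
    rearing_years: float = 3.0  # age at first calving
    lactation_length: int = 305
    mature_weight: float = 400.0  # kg
    milk_fat_pct: float = 4.0
    milk_protein_pct: float = 3.3

    def __post_init__(self):
        if self.lifetime_years <= 0:
            raise ValueError("lifetime must be positive")
        if self.lactation_length > 365:
            raise ValueError("lactation length exceeds one year")

    @property
    def productive_fraction(self) -> float:
        return max(self.lifetime_years - self.rearing_years, 0.0) / self.lifetime_years


@dataclass
class EmissionFactors:
    """Tier-2 emission factors, each carried as a (min, mean, max) range.

    Defaults follow the IPCC (2006) Tier-2 tables for African dairy
    systems; the grazing-land conversion factor is the grassland→cropland
    soil-carbon loss range of Don et al., and the concentrate factor is a
    documented placeholder for a supply-chain emission intensity that must
    be set explicitly for absolute concentrate accounting.
    """

    ym: Param = field(default_factory=lambda: Param(0.065, 0.055, 0.075))
    b0: Param = field(default_factory=lambda: Param(0.13, 0.10, 0.24))
    mcf: Mapping[str, Param] = field(
        default_factory=lambda: {
            "pasture": Param(0.01, 0.005, 0.02),
            "heap": Param(0.04, 0.02, 0.08),
        }
    )
    ef1_soil: Param = field(default_factory=lambda: Param(0.01, 0.003, 0.03))
    ef3_heap: Param = field(default_factory=lambda: Param(0.005, 0.002, 0.01))
    ef3_pasture: Param = field(default_factory=lambda: Param(0.02, 0.007, 0.06))
    ef4_volatilization: Param = field(default_factory=lambda: Param(0.01, 0.002, 0.05))
    ef5_leaching: Param = field(default_factory=lambda: Param(0.0075, 0.0005, 0.025))
    frac_gas: Param = field(default_factory=lambda: Param(0.20, 0.05, 0.50))
    frac_leach: Param = field(default_factory=lambda: Param(0.30, 0.10, 0.80))
    manure_split: Mapping[str, float] = field(
        default_factory=lambda: {"pasture": 0.7, "heap": 0.3}
    )
    luc_ef_grass_to_crop: Param = field(default_factory=lambda: Param(36.7, 22.0, 51.0))
    concentrate_ef: Param = field(default_factory=lambda: Param(0.30, 0.20, 0.40))
    gwp_ch4: float = 25.0
    gwp_n2o: float = 298.0
    vs_ash_fraction: float = 0.08
    milk_n_fraction: float = 0.0053  # kg N per kg FPCM

    def __post_init__(self):
        _check_split(self.manure_split)

    def at_means(self) -> "EmissionFactors":
        """Collapse every range onto its mean (degenerate Params)."""
        kw = {}
        for name in (
            "ym b0 ef1_soil ef3_heap ef3_pasture ef4_volatilization "
            "ef5_leaching frac_gas frac_leach luc_ef_grass_to_crop concentrate_ef"
        ).split():
            kw[name] = Param(getattr(self, name).mean)
        kw["mcf"] = {k: Param(v.mean) for k, v in self.mcf.items()}
        return EmissionFactors(
            manure_split=dict(self.manure_split),
            gwp_ch4=self.gwp_ch4,
            gwp_n2o=self.gwp_n2o,
            vs_ash_fraction=self.vs_ash_fraction,
            milk_n_fraction=self.milk_n_fraction,
            **kw,
        )


def _check_split(split: Mapping[str, float]) -> None:
    total = sum(split.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"manure system split must sum to 1, got {total}")


@dataclass
class EmissionBreakdown:
    """CO2-equivalent emissions by source, kg CO2eq head-1 yr-1."""

    enteric_ch4: float = 0.0
    manure_ch4: float = 0.0
    manure_n2o_direct: float = 0.0
    manure_n2o_indirect: float = 0.0
    soil_n2o_direct: float = 0.0
    soil_n2o_indirect: float = 0.0
    fertilizer_n2o: float = 0.0
    luc_co2: float = 0.0
    concentrate_co2e: float = 0.0

    CATEGORIES = (
        "enteric_ch4 manure_ch4 manure_n2o_direct manure_n2o_indirect "
        "soil_n2o_direct soil_n2o_indirect fertilizer_n2o luc_co2 concentrate_co2e"
    ).split()

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in self.CATEGORIES}

    @property
    def total(self) -> float:
        return float(sum(self.as_dict().values()))

    def __post_init__(self):
        for c, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"negative emission component {c}={v}")


# ---------------------------------------------------------------------------
# Tier-2 kernels
# ---------------------------------------------------------------------------
def annual_concentrate(kg_per_day: float, feeding_days: int) -> float:
    """Annual concentrate fed (kg head-1 yr-1) over the early-lactation window."""
    if kg_per_day < 0:
        raise ValueError("daily ration must be >= 0")
    if feeding_days > 365:
        raise ValueError("feeding days cannot exceed a year")
    return kg_per_day * feeding_days


def _get_feed(feeds: Mapping[str, FeedItem], name: str) -> FeedItem:
    try:
        return feeds[name]
    except KeyError:
        raise KeyError(f"diet component '{name}' has no feed record") from None


def gross_energy_intake(diet: Diet, feeds: Mapping[str, FeedItem]) -> float:
    """Gross energy intake, MJ head-1 yr-1."""
    return float(
        sum(kg * _get_feed(feeds, n).gross_energy_density for n, kg in diet.intakes.items())
    )


def digestible_energy_intake(diet: Diet, feeds: Mapping[str, FeedItem]) -> float:
    return float(
        sum(
            kg * (f := _get_feed(feeds, n)).gross_energy_density * f.dm_digestibility
            for n, kg in diet.intakes.items()
        )
    )


def enteric_ch4(ge: float, ym: float) -> float:
    """Enteric fermentation CH4, kg yr-1: GE × Ym / 55.65."""
    if ge < 0:
        raise ValueError("gross energy must be >= 0")
    if not 0 < ym <= 0.12:
        raise ValueError("Ym outside the plausible (0, 0.12] range")
    return ge * ym / ENERGY_PER_KG_CH4


def vs_excretion(diet: Diet, feeds: Mapping[str, FeedItem], ash_fraction: float = 0.08) -> float:
    """Volatile solids excreted, kg yr-1: undigested DM less ash."""
    return float(
        sum(
            kg * (1.0 - _get_feed(feeds, n).dm_digestibility) * (1.0 - ash_fraction)
            for n, kg in diet.intakes.items()
        )
    )


def manure_ch4(
    vs_excreted: float,
    b0: float,
    mcf_by_system: Mapping[str, float],
    system_split: Mapping[str, float],
) -> float:
    """Manure-management CH4, kg yr-1: VS × B0 × 0.67 × Σ split·MCF."""
    _check_split(system_split)
    weighted_mcf = sum(system_split[s] * mcf_by_system[s] for s in system_split)
    return vs_excreted * b0 * CH4_DENSITY * weighted_mcf


def n_flows(
    diet: Diet,
    feeds: Mapping[str, FeedItem],
    milk_fpcm: float,
    milk_n_fraction: float = 0.0053,
    n_retained: float = 0.0,
) -> dict[str, float]:
    """Nitrogen balance of one cow, kg N yr-1.

    Intake N is crude protein / 6.25 summed over the diet; excreted N is
    intake minus milk N and retained (growth/pregnancy) N.
    """
    n_intake = float(
        sum(kg * _get_feed(feeds, n).crude_protein * CP_TO_N for n, kg in diet.intakes.items())
    )
    n_milk = milk_fpcm * milk_n_fraction
    n_excreted = n_intake - n_milk - n_retained
    if n_excreted < -1e-9:
        raise ValueError(
            f"negative N excretion ({n_excreted:.2f} kg): milk output inconsistent with diet N"
        )
    return {"n_intake": n_intake, "n_milk": n_milk, "n_excreted": max(n_excreted, 0.0)}


def n2o_emissions(
    n_excreted: float,
    n_fertilizer: float,
    f: EmissionFactors,
    system_split: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """N2O emissions by pathway, kg CO2eq yr-1.

    Pasture-deposited excreta N is routed to the soil category (direct
    pasture EF plus volatilisation and leaching); heap-stored N to the
    manure-management category (direct heap EF plus volatilisation).
    Fertilizer N is reported separately.
    """
    split = f.manure_split if system_split is None else system_split
    _check_split(split)
    gwp = N_TO_N2O * f.gwp_n2o

    n_pasture = n_excreted * split.get("pasture", 0.0)
    n_heap = n_excreted * split.get("heap", 0.0)

    manure_direct = n_heap * f.ef3_heap.mean * gwp
    manure_indirect = n_heap * f.frac_gas.mean * f.ef4_volatilization.mean * gwp

    soil_direct = n_pasture * f.ef3_pasture.mean * gwp
    soil_indirect = (
        n_pasture * f.frac_gas.mean * f.ef4_volatilization.mean
        + n_pasture * f.frac_leach.mean * f.ef5_leaching.mean
    ) * gwp

    fert_direct = n_fertilizer * f.ef1_soil.mean * gwp
    fert_indirect = (
        n_fertilizer * f.frac_gas.mean * f.ef4_volatilization.mean
        + n_fertilizer * f.frac_leach.mean * f.ef5_leaching.mean
    ) * gwp

    return {
        "manure_direct": manure_direct,
        "manure_indirect": manure_indirect,
        "soil_direct": soil_direct,
        "soil_indirect": soil_indirect,
        "fertilizer": fert_direct + fert_indirect,
    }


# ---------------------------------------------------------------------------
# Milk model
# ---------------------------------------------------------------------------
#: net energy for maintenance, MJ per kg^0.75 per day (lactating cows)
CFI_MAINTENANCE = 0.386
K_MAINTENANCE = 0.70  # efficiency of ME use for maintenance
K_LACTATION = 0.60  # efficiency of ME use for lactation
ME_FROM_DE = 0.81  # metabolisable/digestible energy ratio
PREGNANCY_OVERHEAD = 0.10  # pregnancy energy as a fraction of maintenance
MILK_PROTEIN_FROM_CP = 0.25  # ceiling on milk protein from dietary CP


def fpcm(raw_milk: float, fat_pct: float = 4.0, protein_pct: float = 3.3) -> float:
    """Fat-and-protein-corrected milk: raw × (0.337 + 0.116·fat% + 0.06·protein%)."""
    return raw_milk * (0.337 + 0.116 * fat_pct + 0.06 * protein_pct)


def lifetime_milk(
    diet: Diet,
    feeds: Mapping[str, FeedItem],
    cow: CowParams | None = None,
    calibration: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Lifetime-averaged milk output, kg FPCM head-1 yr-1.

    Energy balance: metabolisable energy left after maintenance and a
    pregnancy overhead is converted to lactation net energy and divided by
    the energy content of milk; a crude-protein ceiling caps the result.
    The annual figure is averaged over the whole lifetime including the
    unproductive rearing years.

    When ``calibration`` holds an observed yield for ``(diet.lps,
    diet.scenario)`` that value is returned instead, so that scenario
    accounting can run on measured yields.
    """
    cow = cow or CowParams()
    if calibration is not None:
        key = (diet.lps, diet.scenario)
        if key in calibration:
            return float(calibration[key])

    de = digestible_energy_intake(diet, feeds)
    me = de * ME_FROM_DE
    ne_maint = CFI_MAINTENANCE * cow.mature_weight**0.75 * 365.0
    me_required = ne_maint / K_MAINTENANCE * (1.0 + PREGNANCY_OVERHEAD)
    surplus_me = me - me_required
    if surplus_me <= 0:
        warnings.warn("diet does not cover maintenance energy; milk set to 0", stacklevel=2)
        return 0.0
    ne_lact = surplus_me * K_LACTATION
    energy_per_kg_milk = 1.47 + 0.40 * cow.milk_fat_pct  # MJ NE_l per kg
    milk_energy_limited = ne_lact / energy_per_kg_milk

    cp_intake = sum(
        kg * _get_feed(feeds, n).crude_protein for n, kg in diet.intakes.items()
    )
    milk_protein_limited = (
        MILK_PROTEIN_FROM_CP * cp_intake / (cow.milk_protein_pct / 100.0)
    )

    raw = min(milk_energy_limited, milk_protein_limited) * cow.productive_fraction
    return fpcm(raw, cow.milk_fat_pct, cow.milk_protein_pct)


def calibration_from_diet_table(df: pd.DataFrame | None = None) -> dict[tuple[str, str], float]:
    """Milk calibration fixture keyed by (lps, scenario) from the diet table."""
    df = tables.diet_table() if df is None else df
    first = df.drop_duplicates(subset=["lps", "scenario"])
    return {(r.lps, r.scenario): float(r.milk_fpcm) for r in first.itertuples()}


def emission_intensity(total_emissions: float, milk: float) -> float:
    """kg CO2eq per kg FPCM."""
    if milk <= 0:
        raise ValueError("emission intensity undefined for zero milk output")
    return total_emissions / milk


# ---------------------------------------------------------------------------
# Whole-cow accounting
# ---------------------------------------------------------------------------
def cow_emissions(
    diet: Diet,
    feeds: Mapping[str, FeedItem],
    factors: EmissionFactors,
    milk_fpcm: float,
    n_fertilizer: float = 0.0,
    luc_co2: float = 0.0,
    system_split: Mapping[str, float] | None = None,
) -> EmissionBreakdown:
    """Full Tier-2 emission breakdown for one cow-year, kg CO2eq head-1 yr-1.

    ``n_fertilizer`` is the fertilizer N attributable to this cow's feed
    (kg N head-1 yr-1) and ``luc_co2`` an amortised land-use-change charge
    (kg CO2eq head-1 yr-1) computed by the land-budget stage.
    """
    ge = gross_energy_intake(diet, feeds)
    ent = enteric_ch4(ge, factors.ym.mean) * factors.gwp_ch4
    vs = vs_excretion(diet, feeds, factors.vs_ash_fraction)
    split = factors.manure_split if system_split is None else system_split
    man_ch4 = (
        manure_ch4(vs, factors.b0.mean, {k: v.mean for k, v in factors.mcf.items()}, split)
        * factors.gwp_ch4
    )
    flows = n_flows(diet, feeds, milk_fpcm, factors.milk_n_fraction)
    n2o = n2o_emissions(flows["n_excreted"], n_fertilizer, factors, split)
    conc_kg = sum(kg for n, kg in diet.intakes.items() if _get_feed(feeds, n).is_concentrate)
    return EmissionBreakdown(
        enteric_ch4=ent,
        manure_ch4=man_ch4,
        manure_n2o_direct=n2o["manure_direct"],
        manure_n2o_indirect=n2o["manure_indirect"],
        soil_n2o_direct=n2o["soil_direct"],
        soil_n2o_indirect=n2o["soil_indirect"],
        fertilizer_n2o=n2o["fertilizer"],
        luc_co2=luc_co2,
        concentrate_co2e=conc_kg * factors.concentrate_ef.mean,
    )


# ---------------------------------------------------------------------------
# One-at-a-time Latin hypercube uncertainty
# ---------------------------------------------------------------------------
def lhs_uncertainty(
    params: Mapping[str, Param],
    model: Callable[[Mapping[str, float]], float | Mapping[str, float]],
    n_samples: int = 100,
    mode: str = "baseline_full",
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """One-at-a-time uncertainty of ``model`` over parameter ranges.

    ``baseline_full`` draws an LHS sample per parameter (uniform over its
    range, all other parameters at their means); ``scenario_oat``
    evaluates only the minimum and maximum of each range. Per-parameter SD
    contributions are combined in quadrature. ``model`` may return a
    scalar or a mapping of category → value; the result maps each output
    key to ``{"mean": ..., "sd": ...}``.
    """
    if mode not in ("baseline_full", "scenario_oat"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")

    means = {k: p.mean for k, p in params.items()}

    def as_dict(out) -> dict[str, float]:
        return dict(out) if isinstance(out, Mapping) else {"value": float(out)}

    center = as_dict(model(means))
    var_by_key = {k: 0.0 for k in center}
    seeds = np.random.SeedSequence(seed).spawn(len(params))
    for child, (name, p) in zip(seeds, params.items()):
        if p.degenerate:
            continue
        if mode == "baseline_full":
            sampler = qmc.LatinHypercube(d=1, rng=np.random.default_rng(child))
            u = sampler.random(n_samples)[:, 0]
            values = p.min + u * (p.max - p.min)
            outs = [as_dict(model({**means, name: v})) for v in values]
            for key in center:
                var_by_key[key] += float(np.var([o[key] for o in outs], ddof=1))
        else:  # scenario_oat
            lo = as_dict(model({**means, name: p.min}))
            hi = as_dict(model({**means, name: p.max}))
            for key in center:
                var_by_key[key] += ((hi[key] - lo[key]) / 2.0) ** 2

    return {
        key: {"mean": center[key], "sd": float(np.sqrt(var_by_key[key]))} for key in center
    }
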