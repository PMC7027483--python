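"""Built-in parameter tables for the Kenyan dairy-shed analysis.

Three kinds of data live here:

* the per-LPS diet/yield table for the baseline and the three feed
  scenarios (FoCo, FeCo, FoFeCo) at each maize yield-gap level — the
  printed study inputs, used both as scenario definitions and as the milk
  calibration fixture for the herd model;
* the study-area dairy-cow populations and concentrate schedule per
  livestock production system (LPS);
* the concentrate composition and national crop yields behind the
  land-footprint calculation.

Feed-quality attributes and emission-factor ranges are package defaults
(IPCC Tier-2 conventions and the literature values cited in the module
docstrings); everything is overridable through the dataclasses in
:mod:`dairyshed.herd`.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

LPS_CLASSES = ["MRA", "MRH", "MRT", "MIA", "MIH", "MIT"]
SCENARIOS = ["baseline", "FoCo", "FeCo", "FoFeCo"]
YIELD_LEVELS = ["Ya", "Yw50", "Yw80"]

# ---------------------------------------------------------------------------
# Diet and milk-yield table (per cow per year, kg DM unless noted)
# ---------------------------------------------------------------------------
# columns: lps, scenario, yield_level, dmi, pasture, napier, stover, silage,
#          concentrate, milk_fpcm, milk_increase_pct, intensity
_DIET_CSV = """\
lps,scenario,yield_level,dmi,pasture,napier,stover,silage,concentrate,milk_fpcm,milk_increase_pct,intensity
MRA,baseline,Ya,3565,1837,818,874,0,35,1729,,2.64
MRA,FeCo,Ya,4391,1837,818,402,883,450,2489,44.0,2.38
MRA,FeCo,Yw50,4391,1837,818,402,883,450,2489,44.0,2.04
MRA,FeCo,Yw80,4391,1837,818,402,883,450,2489,44.0,1.93
MRA,FoFeCo,Ya,5321,72,2583,0,1765,900,2610,51.0,2.90
MRA,FoFeCo,Yw50,5321,72,2583,0,1765,900,2610,51.0,2.45
MRA,FoFeCo,Yw80,5321,72,2583,0,1765,900,2610,51.0,2.23
MRA,FoCo,Ya,3980,955,1701,874,0,450,2507,45.0,1.76
MRH,baseline,Ya,3621,1233,1321,1031,0,36,1881,,2.40
MRH,FeCo,Ya,4454,1233,1321,554,896,450,2708,44.0,2.16
MRH,FeCo,Yw50,4454,1233,1321,554,896,450,2708,44.0,1.97
MRH,FeCo,Yw80,4454,1233,1321,554,896,450,2708,44.0,1.94
MRH,FoFeCo,Ya,5883,0,3113,77,1793,900,2840,51.0,2.64
MRH,FoFeCo,Yw50,5883,0,3113,77,1793,900,2840,51.0,2.24
MRH,FoFeCo,Yw80,5883,0,3113,77,1793,900,2840,51.0,2.20
MRH,FoCo,Ya,4035,337,2217,1031,0,450,2727,45.0,1.71
MRT,baseline,Ya,3573,1275,1523,740,0,35,1932,,2.33
MRT,FeCo,Ya,4437,1275,1523,304,885,450,2782,44.0,2.10
MRT,FeCo,Yw50,4437,1275,1523,304,885,450,2782,44.0,1.94
MRT,FeCo,Yw80,4437,1275,1523,304,885,450,2782,44.0,1.89
MRT,FoFeCo,Ya,5961,0,3292,0,1769,900,2917,51.0,2.56
MRT,FoFeCo,Yw50,5961,0,3292,0,1769,900,2917,51.0,2.19
MRT,FoFeCo,Yw80,5961,0,3292,0,1769,900,2917,51.0,2.12
MRT,FoCo,Ya,3988,390,2408,740,0,450,2801,45.0,1.67
MIA,baseline,Ya,3565,1837,818,874,0,35,1736,,2.62
MIA,FeCo,Ya,4391,1837,818,402,883,450,2500,44.0,2.36
MIA,FeCo,Yw50,4391,1837,818,402,883,450,2500,44.0,2.05
MIA,FeCo,Yw80,4391,1837,818,402,883,450,2500,44.0,1.93
MIA,FoFeCo,Ya,5321,72,2583,0,1765,900,2621,51.0,2.88
MIA,FoFeCo,Yw50,5321,72,2583,0,1765,900,2621,51.0,2.43
MIA,FoFeCo,Yw80,5321,72,2583,0,1765,900,2621,51.0,2.24
MIA,FoCo,Ya,3980,955,1701,874,0,450,2517,45.0,1.77
MIH,baseline,Ya,3621,1233,1321,1031,0,36,1880,,2.40
MIH,FeCo,Ya,4454,1233,1321,554,896,450,2708,44.0,2.16
MIH,FeCo,Yw50,4454,1233,1321,554,896,450,2708,44.0,1.98
MIH,FeCo,Yw80,4454,1233,1321,554,896,450,2708,44.0,1.95
MIH,FoFeCo,Ya,5883,0,3113,77,1793,900,2839,51.0,2.64
MIH,FoFeCo,Yw50,5883,0,3113,77,1793,900,2839,51.0,2.28
MIH,FoFeCo,Yw80,5883,0,3113,77,1793,900,2839,51.0,2.20
MIH,FoCo,Ya,4035,337,2217,1031,0,450,2726,45.0,1.73
MIT,baseline,Ya,3573,1275,1523,740,0,35,1931,,2.34
MIT,FeCo,Ya,4437,1275,1523,304,885,450,2781,44.0,2.11
MIT,FeCo,Yw50,4437,1275,1523,304,885,450,2781,44.0,1.97
MIT,FeCo,Yw80,4437,1275,1523,304,885,450,2781,44.0,1.92
MIT,FoFeCo,Ya,5961,0,3292,0,1769,900,2916,51.0,2.57
MIT,FoFeCo,Yw50,5961,0,3292,0,1769,900,2916,51.0,2.28
MIT,FoFeCo,Yw80,5961,0,3292,0,1769,900,2916,51.0,2.25
MIT,FoCo,Ya,3988,390,2408,740,0,450,2801,45.0,1.69
"""

#: feed column names in the diet table, in feed-registry order
FEED_COLUMNS = ["pasture", "napier", "stover", "silage", "concentrate"]


def diet_table() -> pd.DataFrame:
    """Per-LPS diet composition, milk yields and emission intensities."""
    df = pd.read_csv(StringIO(_DIET_CSV))
    return df


# ---------------------------------------------------------------------------
# Cow populations and concentrate use per LPS
# ---------------------------------------------------------------------------
_POPULATION_CSV = """\
lps,population_dairy_cows,productive_dairy_cows,baseline_concentrate_t
MRA,246237,147742,16965
MRH,111205,66723,2513
MRT,2443342,1466005,16965
MIA,28845,17307,16965
MIH,20376,12225,3142
MIT,142081,85249,6283
"""


def population_table() -> pd.DataFrame:
    """Dairy-cow populations per LPS.

    ``baseline_concentrate_t`` is a reported fixture (it is not derivable
    from the per-head baseline intakes); the scenario concentrate columns
    are computed from productive cows × the scenario ration instead.
    """
    return pd.read_csv(StringIO(_POPULATION_CSV))


# ---------------------------------------------------------------------------
# Concentrate composition and national crop yields (land footprint)
# ---------------------------------------------------------------------------
_CONCENTRATE_CSV = """\
ingredient,fraction,yield_t_ha,national_area_ha
rice_bran,0.27,2.68,97659
lime,0.04,10.78,1693
wheat_grain,0.27,1.93,85732
maize,0.27,1.52,2092459
sunflower_cake,0.05,0.97,11840
cotton_seed_cake,0.10,0.50,25980
"""


def concentrate_composition() -> pd.DataFrame:
    """Concentrate ingredient fractions and national yields (t/ha)."""
    return pd.read_csv(StringIO(_CONCENTRATE_CSV))


#: total annual concentrate use in the baseline, tonnes (reported fixture)
BASELINE_CONCENTRATE_T = 62834.0

#: worst-case forest→cropland conversion emission factor, Mg CO2eq per ha
FOREST_TO_CROPLAND_EF = 112.7
FOREST_TO_CROPLAND_EF_SD = 3.9

# ---------------------------------------------------------------------------
# Feed quality defaults (DM digestibility, crude protein fraction of DM,
# gross energy MJ per kg DM, cultivated crop yield t DM/ha).
# Pasture grass is grazed from existing grassland and maize stover is a
# crop residue, so neither adds cropland demand; Napier and silage maize do.
# ---------------------------------------------------------------------------
_FEED_CSV = """\
name,dm_digestibility,crude_protein,gross_energy_density,crop_yield,is_concentrate,is_cultivated
pasture,0.55,0.08,18.45,,False,False
napier,0.65,0.12,18.45,12.0,False,True
stover,0.50,0.05,18.45,,False,False
silage,0.68,0.08,18.45,1.6,False,True
concentrate,0.80,0.18,18.45,,True,False
"""


def feed_table() -> pd.DataFrame:
    """Default feed-quality attributes for the five diet components.

    The silage crop yield is the actual fodder-maize yield (Ya) and is
    overridden per yield-gap level by :class:`dairyshed.landbudget.YieldGapLevel`.
    """
    return pd.read_csv(StringIO(_FEED_CSV))


# Maize yield-gap defaults: actual yield Ya and water-limited potential Yw
# (t DM/ha), with above-ground N uptake per tonne of yield. The defaults
# put Ya at ~23% of Yw, inside the 30%–82% yield-gap range reported for the
# Kenyan highlands, and give applied fertilizer-N rates of ~81 (Yw50) and
# ~170 (Yw80) kg N/ha at 33% fertilizer NUE.
MAIZE_YA = 1.6
MAIZE_YW = 7.0
MAIZE_N_UPTAKE_PER_T = 14.0  # kg N per t DM above-ground biomass
NUE_FERTILIZER = 0.33
NUE_MANURE = 0.20
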