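"""Concentrate demand, its land footprint, and worst-case deforestation.

The medium-intensification scenarios feed 3 kg concentrate/day over 150
lactation days (450 kg/cow/yr), the high scenario 6 kg/day (900 kg).
Multiplying by the productive cow population per livestock production
system gives national concentrate demand; ingredient composition and
national crop yields convert that into a land footprint, and a
forest-to-cropland emission factor bounds the worst-case carbon cost.
"""

from dairyshed import tables
from dairyshed.herd import annual_concentrate
from dairyshed.landbudget import (
    concentrate_demand,
    concentrate_footprint,
    worst_case_deforestation,
)

print("annual concentrate per cow: medium",
      annual_concentrate(3, 150), "kg, high", annual_concentrate(6, 150), "kg")

pops = tables.population_table().set_index("lps")["productive_dairy_cows"]
medium = concentrate_demand(pops, 450.0)
high = concentrate_demand(pops, 900.0)
print(f"medium-intensification demand: {medium['total']:,.0f} t/yr")
print(f"high-intensification demand:   {high['total']:,.0f} t/yr")

for label, total in (("medium", medium["total"]), ("high", high["total"])):
    fp = concentrate_footprint(total).set_index("ingredient")
    area = float(fp.loc["total", "scenario_ha"])
    mt, sd = worst_case_deforestation(area)
    print(f"{label}: land footprint {area:,.0f} ha beyond the baseline; "
          f"if cleared from forest: {mt:.0f} +/- {sd:.0f} Mt CO2eq")
# The footprint is the extra cropland (beyond today's concentrate use)
# needed to grow the ingredients; the Mt figures are the carbon-leakage
# risk if that expansion displaced secondary forest.
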