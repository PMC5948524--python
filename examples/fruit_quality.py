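"""Fruit-damage indices and harvesting efficiency on worked numbers.

Colour index CI = L* (b* - a*) / 100 tracks maturity/browning; bruising
incidence BI weights the none/low/severe bruise categories 0/1/2; harvest
efficiency summarises row time, fruit removal and ground losses.
"""

from olivescan.datasets import load_harvest_efficiency_survey
from olivescan.fruit import (BruiseCounts, FruitColour, HarvestPlot,
                             bruising_incidence, colour_index,
                             harvest_efficiency)

green = FruitColour(L_star=50.0, a_star=-10.0, b_star=20.0)
brown = FruitColour(L_star=42.0, a_star=4.0, b_star=9.0)
print(f"colour index, green-yellow fruit: {colour_index(green):.1f}")
print(f"colour index, brownish fruit:     {colour_index(brown):.1f} "
      "(lower = duller, more damaged)")

counts = BruiseCounts(n0=40, nl=50, ns=10)
print(f"bruising incidence for 40/50/10 none/low/severe: "
      f"{bruising_incidence(counts):.2f} on the 0-2 scale")

plot = HarvestPlot(row_time_h=0.16, row_area_ha=0.1, total_yield_kg=1710.0,
                   fruit_left_on_tree_kg=8.6, ground_sample_weight_kg=0.225)
eff = harvest_efficiency(plot)
print(f"\nexample row: {eff.time_per_ha:.1f} h/ha, removal {eff.removal_pct:.1f} %, "
      f"ground loss {eff.ground_loss_pct:.1f} % of production")

print("\npublished per-treatment efficiency survey:")
print(load_harvest_efficiency_survey().to_string(index=False))
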