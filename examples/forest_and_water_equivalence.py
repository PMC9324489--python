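"""Express an annual human-evaporation volume in equivalence currencies.

Takes a 14.0 million m³ annual total (a megacity-scale figure) and asks:
how much broadleaf plantation evaporates that much per year, what fraction
of natural urban evapotranspiration is it, and how does it compare with the
total water use of some European cities?
"""

from citysweat import comparison_report
from citysweat.compare import (
    equivalent_population_density,
    human_vs_green_ratio,
)

report = comparison_report(
    annual_total_m3=14.0e6, mean_intensity_mm=10.37, natural_et_mm=348.0
)

print(f"forest ET per unit area : {report['forest_et_m3_per_km2']:,.0f} m³/km²/yr")
area = report["equivalent_forest_area_km2"]
print(f"equivalent forest area  : {area['rounded']:.1f} km² (raw {area['raw']:.2f})")
frac = report["natural_et_fraction_pct"]
print(f"fraction of natural ET  : {frac['raw']:.2f}% (≈{frac['rounded']:.0f}%)")
print("multiples of annual city water use:")
for city, mult in report["water_use_multiples"].items():
    print(f"  {city:10s} {mult:5.2f}×")

# district-level green-space parity from reported volumes (thousand m³)
ratio = human_vs_green_ratio(707.3, 1347.8)
density = equivalent_population_density(21_800.0, 1347.8, 707.3)
print(
    f"\ndense-district example: humans evaporate {ratio.value:.2f}% of what the"
    f"\ndistrict's green space does; parity would need {density.value:,.0f}"
    " people/km²."
)
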