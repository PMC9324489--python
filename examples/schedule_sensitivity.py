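"""How sensitive is the annual total to the assumed daily time allocation?

Survey data bound sleep at 6–10 h and moderate activity at 0.5–2 h per day.
This script evaluates the annual per-person total over a grid of allocations
and reports the extreme relative changes against the 8/14/2 baseline.
"""

from citysweat import (
    DailySchedule,
    SensitivityBounds,
    WeatherSpec,
    default_season_configs,
    generate_weather,
    schedule_sensitivity,
)

weather = generate_weather(WeatherSpec(seed=0), year=2020)
res = schedule_sensitivity(
    SensitivityBounds(), DailySchedule(), weather, default_season_configs()
)

print(f"baseline annual total : {res.baseline_litres:.1f} L/person")
print(f"range of change       : {res.min_pct:+.2f}% .. {res.max_pct:+.2f}%")
print(f"minimum at (sleep, moderate) = {res.argmin} h")
print(f"maximum at (sleep, moderate) = {res.argmax} h")
print(
    "\nMore sleep lowers the total (sleep has the lowest metabolic rate);"
    "\nmore moderate activity raises it (220 vs 75 W/m² for light work), so"
    "\nthe extremes sit at the corners of the bounds and the range brackets"
    "\nthe baseline."
)
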