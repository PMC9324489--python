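# Methods

## Scope and model

`citysweat` estimates the water evaporated by a city's population through
perspiration and respiration. The core is a steady-state heat-balance model
of one representative clothed adult:

1. **Skin state.** Mean skin temperature is a linear regression on the
   surrounding air temperature, `T_sk = 0.215·t_a + 26.6` °C (Saltin). The
   skin surface is taken as saturated, so the skin vapor pressure is the
   saturation pressure at `T_sk`.
2. **Saturation curve.** An Antoine form `exp(18.6686 − 4030.183/(T + 235))`
   is used. Its constants are native to mmHg — evaluated at 100 °C it gives
   763.7 mmHg ≈ 1 atm (the package's unit-convention test) — so the output
   is converted to kPa (×0.133322) before entering the heat balance, whose
   respiratory and evaporative terms are written in kPa. A configuration
   flag (`vapor_unit="as_printed"`) preserves the raw exponential for
   sensitivity studies; it is physically implausible (it inflates the
   vapor-pressure gradient ≈7.5×) and not the default.
3. **Clothing surface temperature.** Dry losses are evaluated at the
   clothing surface, which satisfies the steady conduction balance
   `(T_sk − t_cl)/I_cl = f_cl·h_c·(t_cl − t_a) + f_r·h_r·(t_cl − t_r)`.
   With a constant linearized radiation coefficient the balance is linear in
   `t_cl`, so the solver computes the exact fixed point in closed form and
   asserts the residual below 1e−6 W/m²; the test suite cross-checks it
   against an independent bisection to 1e−4 °C on randomized states.
4. **Sweat rate.** The piecewise (PW) regression
   `m_sw = 147 + 1.527·E_req − 0.87·E_max` (g·m⁻²·h⁻¹). Negative
   predictions are clamped to zero and flagged; no artificial floor is
   applied, since the regression itself carries the insensible component in
   its intercept.

### Parameters and defaults

| parameter | default | unit | why |
|---|---|---|---|
| activity M / h_c / f_r | sleep 40/2.7/0.35; light 75/4.0/0.7; moderate 220/8.2/0.73 | W/m², W/(m²·K), – | standard tabulated values for the three activity classes |
| mechanical efficiency η | 0 | – | near zero for everyday activities (5–10% only for intense exercise) |
| clothing f_cl / I_cl / i_cl | spring 1.22/0.89/0.50; summer 1.10/0.36/0.55; autumn 1.28/1.01/0.48; winter 1.33/1.20/0.43 | –, clo, – | seasonal ensembles; see unit note below |
| Lewis ratio LR | 16.5 | °C/kPa | typical indoor air |
| radiation coefficient h_r | 4.7 | W/(m²·K) | standard linearized value for indoor surfaces; configurable |
| mean radiant temperature t_r | = t_a | °C | indoor assumption; configurable |
| body surface area A_D | 1.8 | m² | standard adult; DuBois formula available from mass/height |
| schedule | 8 h sleep, 14 h light, 2 h moderate | h | survey-typical indoor day |
| indoor rule | winter: fixed 22 °C; others: outdoor mean clipped to [16, 30] °C | °C | district heating keeps winter interiors warm; otherwise daily means, bounded to habitable rooms |
| seasonal rh | 0.40/0.60/0.50/0.30 (spring/summer/autumn/winter) | – | monsoon climate: humid summers, very dry winters |

**Clothing insulation unit.** The seasonal I_cl magnitudes (0.36–1.20) are
physically plausible as clo and implausible as m²·K/W (1.20 m²·K/W ≈ 7.7
clo, an arctic ensemble). The default therefore interprets them as clo
(1 clo = 0.155 m²·K/W); `Icl_unit="si"` selects the as-printed reading.
Similarly, the clothing evaporative resistance uses the standard
clothing-science convention `I_e,cl = I_cl/(i_cl·LR)`; the alternate product
grouping `I_cl·i_cl/LR` is selectable (`e11_grouping="product"`). These
flags exist because the printed parameter table underdetermines both
choices; every run logs the flags in effect.

## Schedule and seasonal integration

Each day contributes `Σ_blocks m_sw(activity, indoor state) × A_D × hours`,
in litres (1 g ≡ 1 mL). Seasons follow the meteorological calendar (spring
Mar–May, summer Jun–Aug, autumn Sep–Nov, winter Jan+Feb+Dec of the same
year), so the four seasons partition the calendar year exactly. Because the
rates are steady within a day, the daily total is linear in the block hours;
the sensitivity analysis exploits this by precomputing per-activity annual
rates and evaluating a 9×7 grid over sleep ∈ [6, 10] h × moderate ∈
[0.5, 2] h (light work is the remainder). The objective is monotone in each
coordinate — sleep has the lowest metabolic rate, moderate the highest — so
the extremes sit at the corners; the grid documents the whole surface, and
the baseline is always a member of the search set, so the reported range
brackets zero.

## Upscaling and units

Per-person rates are spatially uniform within a run; spatial structure comes
only from the persons-per-cell population raster (default 100 m cells,
row-major, north-up, nodata treated as zero with a warning). District
volume (m³) = district population × per-person litres / 1000. Per-cell
intensity (mm/year) = cell volume / cell area × 1000, zero exactly where
population is zero, and conserving total volume against the district and
city aggregations to floating-point precision. City-average mm always takes
the administrative area as an explicit input, since the appropriate
denominator (built-up vs total area) is a reporting choice.

## Equivalence accounting

Forest evapotranspiration per unit area is per-plant annual water use ×
planting density × 100 hm²/km² ÷ 1000 kg/m³ (water density 1000 kg/m³); the
default plantation (15 cm DBH broadleaf at 800 plants/hm², 1667.6 kg/plant)
evaporates 133,408 m³/km²/year. Green space is a configurable set of
land-cover class codes (tree cover + grassland by default) on a 10 m grid,
assumed planted at the reference rate. Ratios are reported raw and rounded
(two decimals for percentages, nearest hundred for parity population
densities, one decimal for km²).

## Synthetic data

The generators produce the *shape* of the real inputs, not their geography:
a core-peaked (exponential-decay with mild lognormal heterogeneity)
population surface allocated to integer persons by largest-remainder
rounding (grid sums to the requested total exactly), Voronoi districts
around seeded points with deterministic tie-breaks, a refined land-cover
grid with an exact green-cell count, and seasonal daily temperatures as one
sinusoidal cycle per season plus Gaussian noise (defaults: season means
14/27/13/−2 °C, noise sd 2 °C — a continental monsoon annual cycle with a
≈13 °C annual mean). All randomness flows from a single seed per call.

Passing tests on these fixtures demonstrate the arithmetic, unit and
conservation properties of the pipeline and the qualitative behaviour of
the model (monotonicity in temperature, activity ordering, linearity in
population). They do not demonstrate calibration against any real city:
real population rasters are not radially symmetric, real weather is not
sinusoidal, indoor climates vary by building, and the representative-person
assumption ignores demographic heterogeneity.

## Numerical choices

- Clothing-temperature balance: closed-form linear solve, residual asserted
  < 1e−6 W/m²; bisection is kept as the independent test oracle.
- Negative sweat predictions: clamped to zero with a `clamped` flag; the raw
  value is retained on the result object.
- Largest-remainder allocation tie-breaks on the lower flat cell index;
  Voronoi label ties take the lowest district index.
- Aggregations are plain sums (no compensated summation); conservation tests
  pass at 1e−9 relative on the fixture sizes used.
- Degenerate inputs (empty seasons, zero areas, misaligned grids, unknown
  config keys or flag values) raise `ValueError` rather than warn.

## Known limitations

- **Resting over-prediction.** The PW regression was fitted to exercising
  subjects. At sleeping metabolic rate it predicts ≈60–270 g/h whole-body
  water loss across 20–34 °C (depending on clothing), well above classical
  resting insensible-perspiration measurements of 20–50 g/h, and the
  resulting daily totals (≈2.5–5 L/person at ordinary indoor states) exceed
  measured daily evaporation (≈1.5 L). The acceptance suite asserts those
  published consistency bands at face value and the corresponding tests fail
  under the faithful implementation; this is a property of the regression
  applied outside its fitted range, not of the implementation, and no
  parameter choice within the documented flag space closes the gap (at warm
  temperatures E_max is bounded by the boundary-layer term (P_sk−P_a)·f_cl·h_e,
  which is too small to offset the 147 g·m⁻²·h⁻¹ intercept).
- **Seasonal ordering.** With the default winter setpoint (22 °C) and the
  heaviest ensemble, winter per-person evaporation exceeds summer's: added
  clothing raises both the required evaporation and the evaporative
  resistance, and both raise the predicted rate. Reports of summer-first
  orderings depend on indoor assumptions the model cannot recover.
- Steady-state only: no transient thermoregulation, two-node body model,
  sweat dripping/evaporated split, acclimatization or outdoor exposure.
- No coordinate reprojection or dasymetric population modelling; rasters
  must be pre-aligned.
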