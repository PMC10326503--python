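# Methods

## Model overview and assumptions

`hexstream` simulates the juvenile life stage of obligately
lake-migrating Atlantic salmon and brown trout in a single river reach.
The life cycle is deliberately discontinuous: adults are injected each
autumn by an arrival schedule, spawn once, and die (they receive zero
food intake everywhere and lose 40 % of their weight at spawning, so
poor-condition mortality removes them); juveniles grow in the reach
until a length-dependent stochastic out-migration removes them. There is
no adult return loop, no angling mortality, no piscivorous-fish
predation (the piscivory length, 100 cm, is unreachable by design), and
turbidity is fixed at zero (effects are negligible below 5 NTU).

Both species share one length-based dominance hierarchy and the same
survival parameterization except where biology differs: spawning
windows (trout 5 Oct–10 Nov, salmon 1 Nov–5 Dec), fecundity,
length–weight allometry, redd development rates, and outmigration
anchors.

### Scheduling

The simulator walks the hourly environment series. Within an hour the
order is: new-year update (ages, superindividual splitting) at 00 h on
1 January; biggest-length update and daily reporting at 00 h; arrivals
at 10 h; spawning, then redd survival → development → emergence at the
first daylight hour; then, if a model time step closes at this hour,
fish survival draws and growth over the elapsed step, reporting, and
habitat selection for the next step. A step closes when the day/night
phase flips, the flow changes by more than 5 % (relative), or the
temperature changes by more than 0.5 °C since the step began; with the
daily-constant temperatures and near-constant regulated flows of this
application this yields mostly day/night stepping with an extra midnight
boundary when the daily temperature moves. Conditions are constant
within a step by construction, so feeding and survival rates are
evaluated once per step at its start.

Fish created mid-step (arrivals, emerging fry) are buffered and join the
population at the next step boundary, after the closing survival draws:
a fish is never exposed to mortality for a step during which it did not
exist.

### Feeding, growth and habitat selection

Feeding bookkeeping is done in rates (g/h). A cell's drift supply rate
is `habDriftConc · velocity · depth · cellWidth · 3600` with the cell
width taken as area divided by the hexagon's north–south extent; its
search supply rate is `habSearchProd · cellArea`. Dominant fish debit
supply, velocity-shelter area and hiding-cover area first (a fish
occupies `length²` cm² of shelter or cover, times `nRep`). Intake is the
better of drift and search feeding, capped by the remaining supply and
by maximum consumption. Growth converts net energy (intake ×
`habPreyEnergyDensity` − respiration) at `fishEnergyDensity` = 5900 J/g;
weight may fall but length only rises, and only to keep the condition
factor at or below 1.

Habitat selection maximises
`S_risks^H · S_starv(H) · ln(1 + expectedLength/biggestLength)` with
`H = fishFitnessHorizon` (90 d). `S_risks` is the product of the five
non-starvation survival sources at the candidate cell; starvation is
handled separately by `S_starv`, the poor-condition survival evaluated
at the condition factor projected to the end of the horizon (a
deliberate end-point approximation of the horizon integral, which keeps
the candidate evaluation vectorisable). `biggestLength` is the longest
living fish, floored at 1.5× the minimum spawning length (37.5 cm).

### Survival and out-migration

Each source's daily survival is converted to the step length as
`s^(h/24)` and drawn independently per fish from a per-fish random
stream; the first failing source is recorded as the cause of death.
Out-migration is drawn last — an out-migrant must have survived the
step — and is logged (with `nRep` and length), never counted as a death.
The per-fish streams are seeded as `(run seed, 1, fish id)`, so results
are reproducible and independent of processing order; population-level
events (arrival attributes, redd survival, emergence) use a single
`(run seed, 0)` stream.

### Redds

Egg losses are applied daily at the first daylight hour, in the order
dewatering (depth ≤ 0), scour, low temperature, high temperature; egg
counts stay integral through unbiased stochastic rounding
(floor + Bernoulli on the remainder). Scour destroys the whole redd
when the dimensionless shear stress `habShearParamA · Qpeak^habShearParamB`
exceeds the critical Shields value 0.045 — a threshold chosen so that,
with the default shear parameters, scour cannot occur below the
30 m³/s flow cap, consistent with scour being a negligible egg-mortality
source in the target system. Superimposition is resolved when a new
redd is dug: each existing redd in the cell is hit with probability
`min(1, reddSize / cellGravelArea)` and loses a Uniform(0,1) fraction of
its eggs. The new redd itself is not damaged. Gravel area is not
depleted by existing redds; superimposition already penalises crowding.

Development adds `A + B·T + C·T²` per day at the daily mean temperature
(eggs are buried and lack behaviour, so sub-daily variation is ignored).
Once development reaches 1, day *k* of emergence converts *k*/10 of the
remaining eggs (day 10 empties the redd); emerging eggs become
superindividuals of `juveSuperindividualRatio` (default 10) eggs each,
rounded upward to whole fish.

## Parameters that matter most

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `habDriftConc` | 1.1e-9 | g/cm³ | calibrated food level; linked with `habSearchProd` in calibration |
| `habSearchProd` | 1.75e-6 | g/(h·cm²) | calibrated food level |
| `mortFishTerrPredDayMin` | 0.9775 | — | calibrated daytime terrestrial-predation floor |
| `mortFishOutmigrationL1/L9` | sp.-specific | cm | staying = 0.1 / 0.9 anchors; fitted from cumulative remain targets |
| `fishSpawnMaxTemp` | 10 | °C | binds trout spawning on warm autumns; subject of a sensitivity sweep |
| `juveSuperindividualRatio` | 10 | — | aggregation of fry; large values distort per-cell resource competition |
| `fishFitnessHorizon` | 90 | d | habitat-selection lookahead |

The full registries (about 150 named parameters) live in
`core_math.SpeciesParams` and `core_math.ReachParams` with the field's
conventional names, and can be loaded from flat `name = value` files;
unknown names are a hard error so typos cannot silently fall back to
defaults.

The salmon fecundity default is the constant model `A = 210`, `B = 0`
(the best fit to the stripping data was a constant); the printed source
for this constant is typographically ambiguous, so the registry treats
it as freely configurable and the quantitative tests use trout
fecundity only.

## Synthetic generators

The synthetic reach emulates a restored rapids below a dam: flat-topped
hexagons at 1.5 m east–west spacing, monotone power-law depth/velocity
ratings (defaults `26·Q^0.42` cm and `25·Q^0.38` cm/s) with lognormal
(σ = 0.25) per-cell spatial factors over the standard 20-discharge
lookup grid, Beta-distributed shelter and cover fractions, one
contiguous spawning-gravel patch covering about a tenth of the cells,
and U/D end columns. The synthetic environment provides a near-constant
3 m³/s regulated flow with AR(1) excursions and rare multi-day spikes,
and a water temperature following a seasonal sinusoid between about 0.5
and 20 °C (mean 10.25, amplitude 9.75, peak at day 200) with
autocorrelated daily noise, repeated across each day's 24 hours —
mirroring the use of daily mean temperature as hourly input. Turbidity
is zero.

What the generators do **not** emulate: real hydraulic topology
(backwaters, margins, longitudinal gradients), correlated
depth–velocity–cover structure, flow-dependent wetted-area change at
the reach margins, inter-annual temperature trends, and observation
error in electrofishing. Tests passing on synthetic inputs therefore
demonstrate internal correctness (conservation, calibration recovery,
sensitivity direction, parameter recovery), not field validity for any
particular river.

## Numerical choices

* Anchored logistics clamp their exponent at ±700 to avoid overflow;
  outputs are strictly inside (0, 1) for arguments within a few anchor
  spans.
* Hydraulic lookups interpolate linearly between tabulated flows and
  clamp (with a warning) outside 0.5–30 m³/s; flows are capped at
  30 m³/s by the scenario builders anyway.
* Cell membership of the hex grid is centroid-inside; adjacency comes
  from shared edges. Adjacent-column neighbours sit √3·s apart with a
  horizontal component of exactly one east–west spacing.
* Ties in habitat selection resolve to the first candidate index
  (lowest cell index, feed before hide); ties in spawning-site quality
  are broken by the per-cell uncertainty factor `U`, which exists
  precisely to avoid deterministic pile-ups on one best cell.
* Day length uses the standard solar-declination formula (default
  latitude 59° N) extended by `habTwilightLength` (0.5 h) at each end;
  every calendar day is guaranteed at least one daylight hour.
* The outmigration anchor solver nests the cumulative-product forward
  computation inside a two-dimensional root find (several starts,
  residual < 1e-6). The other fits use `scipy.optimize.least_squares`
  from closed-form linear starts; optimizer identity is irrelevant, the
  objective value is what is checked.
* Degenerate inputs are first-class: constant air temperature collapses
  the residual regression to intercept-only; a female finding no
  positive-quality spawning cell does not spawn; an empty run (no fish,
  no arrivals) completes with empty outputs.

## Scaled-down experiment sizes

The self-calibration and sensitivity checks in the test suite run the
full simulator at reduced problem sizes chosen as the smallest
configurations in which the tested mechanism operates: a 48–80-cell
reach, one to two simulated years, 4–20 arriving spawners per species,
and a superindividual ratio of 10–100. The calibration check reads the
simulated 0+ cohort in mid-June (as in the observation series, which
includes June surveys), when the cohort is reliably present; by
September a small superindividual cohort can be extinguished by
demographic stochasticity, which is a property of small scale, not of
the calibration machinery.

## Known limitations

* The expected-maturity growth projection and the starvation term use
  end-of-horizon state, not path integrals.
* Drift depletion regenerates fully each step; `habDriftRegenDist` is
  retained as a documented constant but does not throttle regeneration
  within a step.
* The velocity experienced by a hiding fish is zero for respiration but
  the cell mean for predation/velocity risk; sub-cell hydraulics are not
  modelled.
* Superindividual resource consumption (×`nRep`) makes results sensitive
  to the ratio in small cells; the ratio used for calibration should be
  retained for experiments.
* Spawning females select among cells reachable within their movement
  radius, not the whole reach; with very small reaches this is the whole
  reach anyway.
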