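# Methods

## The water balance

The soil profile down to `profile_depth_cm` (default 60 cm) is a single
store, tracked as a soil moisture deficit SMD ≥ 0 mm with 0 meaning the
profile is at field capacity; the deficit grows as the soil dries. The daily
update is

    AET  = PET · f · s(SMD_prev)
    d    = SMD_prev + AET − (Rain + Irrigation)
    Drainage = max(0, −d),    SMD_next = max(0, d)

Assumptions: daily resolution; no runoff partitioning, capillary rise, snow,
or multi-layer physics; any water beyond the remaining deficit drains the
same day. Within a day the order evapotranspire → add water → partition
drainage is arbitrary at daily resolution; it is collapsed into the single
provisional-deficit formula above so the accounting is auditable. Nitrogen
treatments are labels carried through the tables; they do not alter the
water model.

Two corrections tie the model to observations:

* **Canopy-adjusted PET.** `f` is the daily canopy-cover fraction; before
  full closure actual evapotranspiration is well below PET, and `f = 0`
  during fallow means no transpiration at all.
* **Observation resets.** On a day with a probe-derived profile storage `S`,
  the deficit is reset to `max(0, FC − S)` *after* that day's model step.
  Stepping first means a prediction always exists for the day, so the signed
  residual (model − observation-implied) quantifies drift between
  observations. An observation wetter than FC resets to 0 and is logged as
  supersaturation; no retroactive drainage is invented for it.

The stress factor `s` is 1 unless `stress_model="linear"`, in which case
`s = clamp((TAW − SMD)/(TAW − RAW), 0, 1)`: unrestricted transpiration until
the readily available water RAW (mm) is used, declining linearly to zero at
the total available water TAW (mm). It defaults to off because the two
corrections above are the documented behaviour of the system being modelled;
the linear reduction is provided for fidelity experiments. With stress off,
SMD has no upper cap; a warning is logged if it passes `taw_mm` when that is
configured.

Initialisation: the default `smd_init="from first observation"` anchors the
state at the first forcing day's observed storage and refuses to run before
any observation exists — guessing an initial deficit silently would make
early drainage unfalsifiable. The pipeline glue therefore slices each plot's
run to start at its first probe date.

## Canopy cover

NDVI is standardised across instruments by per-instrument linear calibration
(`gain·raw + offset`), identity by default since no cross-instrument mapping
is given for the trial instruments; the calibration table is the user's
responsibility. Cover is linear in NDVI between a bare-soil baseline
`ndvi_bare = 0.15` (cover 0) and the closure threshold `ndvi_closure = 0.75`
(cover 1), clamped outside. The closure end is the field-calibrated
assumption for adequately watered vegetable crops; the bare baseline is this
package's choice — bare soil has NDVI well above 0 — and is prominently
configurable because it shifts early-season AET.

Daily interpolation per crop season [emergence, harvest]: cover is 0 before
emergence, after harvest and on fallow days; observations outside any crop
window are dropped with a warning; the series is piecewise-linear in time
through the retained observations (canopy development is assumed linear
between emergence and closure), anchored at (emergence, 0) when no
observation falls on the emergence day. Full closure is treated as an
absorbing state between observations: after an observation at cover 1 the
series holds 1 until the next observation, whose own value is honoured
exactly — so an observed senescence decline appears as a step at the
observation date rather than an invented downward ramp, and no senescence
model is imposed. After the last observation the last value is held to
harvest.

The crop calendar lists one row per season (plot, crop, sowing, emergence,
harvest). Fallow intervals are the complement of the [sowing, harvest]
windows; representing them implicitly keeps "fallow never overlaps a crop"
true by construction and spares the data-entry team a sixth table.

## Profile storage and field capacity

Storage over the accounting profile is Σ θᵢ · thicknessᵢ(mm) over probe
layers intersected with [0, profile_depth_cm]; a layer reaching deeper
contributes only its intersected thickness, and a coverage gap inside the
profile is an error rather than an extrapolation. Layer boundaries are cm
below the surface, half-open [top, bottom).

Field capacity is estimated per plot from storages observed during winter
fallow — the recurring `fallow_window` month range (default June–August),
with crop-standing dates additionally excluded by the pipeline — on the
assumption that with minimal evaporation the profile returns to capacity
then. `fc_rule="max"` (default) takes the wettest such reading, matching the
"capacity is reached in winter" reasoning; `fc_rule="quantile"` with
`fc_quantile=0.95` guards against a single anomalous reading at the cost of
a small low bias. Estimation fails loudly when no winter reading exists:
every deficit downstream is relative to FC, so it must never default. Plots
are estimated independently; no pooling across plots is attempted.

## Drainage events

Events are maximal runs of days with drainage > 0; runs separated by at most
`event_merge_gap_days` (default 1) dry days are merged, and merged events
with total < `event_min_mm` (default 1 mm) are discarded. Both thresholds
are artifact conventions — discrete labelled events need a segmentation
rule, and these defaults keep one overnight pause from splitting a storm
while suppressing sub-millimetre noise — and both are configuration fields.
Lags are measured from the event *end* to the first reference date on or
after it, because leachate is collected after drainage completes. Merging
preserves drained mass and filtering only removes it, so the event total
never exceeds the trajectory total.

## Synthetic trials

The generator emulates a southern-hemisphere irrigated annual-crop trial:
PET is a day-of-year sinusoid peaking in mid-January (mean 2.5, amplitude
2.0 mm/day → ~0.5 midwinter, ~4.5 midsummer); rain is Bernoulli occurrence
(p = 0.3) × gamma amounts (mean 6 mm, shape 0.7), giving ~660 mm/year with
realistic dry-day structure. One crop per year is sown 15 September, emerges
a fortnight later, closes canopy 56 days after emergence, and is harvested
1 March; irrigation applies 25 mm on cropped days once the previous day's
deficit exceeds 30 mm. True field capacity is drawn per plot as 0.28–0.32 of
the profile depth in mm (168–192 mm at 60 cm). Truth trajectories are
produced by running the forward model above from a full profile at the
1 June trial start.

Observations are then sampled from truth: NDVI fortnightly from emergence
through the inverse cover map plus Gaussian noise (default sd 0.03, two
alternating instruments), and probe readings fortnightly from the trial
start as per-layer θ = storage/depth plus per-layer Gaussian noise (default
sd 0.01, three layers) — per layer, not per profile, so aggregation really
averages. Two constructions make the zero-noise case an exact closure test:
the true cover curve's knots (emergence, closure) lie on the fortnightly
observation grid, so piecewise-linear interpolation of noise-free
observations is an exact inverse; and the first probe reading falls on
1 June with zero deficit, so the winter maximum recovers FC exactly.

What the generator does **not** emulate: calibrated stochastic-weather
realism (no autocorrelated storm sequences), spatial correlation between
plots, instrument drift or bias (noise is zero-mean), senescence in the true
cover curve, and data-entry errors. Passing tests therefore demonstrate that
the pipeline inverts its own forward model under realistic sparsity and
noise — not that the bucket model is an adequate physical description of any
particular soil.

## Incremental execution

Stages declare their input files, the configuration keys they read, and
their upstream stages. A stage's fingerprint is the SHA-256 of (a manually
bumped per-stage code-version tag, the content digests of its declared
files, its declared parameter values, its upstream fingerprints); it
re-executes exactly when the fingerprint differs from the cached one.
Content hashing rather than modification times means copied-but-identical
files never trigger work, and chaining upstream fingerprints propagates any
change to all DAG descendants. The cache is one JSON manifest beside the
outputs, written atomically after each successful stage; an advisory lock
file guards the single-user case, and a failed stage halts the run with its
cache entry untouched so the next run retries it. Execution order is Kahn's
algorithm with ties broken by stage name, so plans are deterministic.

## Numerical conventions

All depths are mm of water, dates are calendar days (ISO-8601 in files),
and θ is a volume fraction bounded by 0.7 (porosity). Equality tolerances in
tests are 1e-9 mm unless a check is exact by construction; the balance step
groups `Rain + Irrigation` before subtraction so that independent
re-implementations of the same accounting agree bit-for-bit. CSV round-trips
write floats with 12 significant digits (well inside the 1e-9 guarantee).
Test problem sizes: the closure fixture is a 2-plot 2-year trial, the mass-
conservation sweep an 8-plot 10-year trial, FC recovery uses 20 single-plot
replicates, and oracle equivalence uses 100 random-year fixtures plus the
exhaustive enumeration of all drainage series of length ≤ 12 over
{0, 1, 3} mm for merge gaps 0–2.

## Known limitations

* FC by the max rule is biased high under observation noise (a maximum of
  noisy readings); the quantile rule trades that for a small low bias.
* The reset correction trusts observations absolutely; a bad probe reading
  propagates until the next one.
* Cover between observations after closure is held at 1, which overstates
  AET if senescence happens between fortnightly visits.
* Deficits above TAW are physically implausible but not prevented with the
  stress model off (a warning is logged when `taw_mm` is configured).
* The orchestrator's code-version tags are bumped manually; editing a
  stage's code without bumping its tag reuses stale outputs.
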