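# Methods

## The estimation problem

A carcass staked in front of a rapid-fire camera trap loses mass to three
sinks: vertebrate scavengers eating in place, vertebrate scavengers
removing the whole carcass, and everything else (invertebrates, microbial
decay, desiccation). Only the start and end masses are weighed; the camera
record tells us *who was present, doing what, for how long*. The package
estimates the species-level partition of the lost biomass from those two
information sources, and ships a simulator whose hidden ledger makes the
estimator's error measurable.

## Observation extraction

Frames are grouped per (carcass, species): a presence run continues while
inter-frame gaps stay within `gap_threshold_s`, and is split into
observations at each behaviour change. The default threshold is 60 s:
rapid-fire cameras re-trigger within ~0.5 s while an animal is present, so
any gap of minutes is a genuine departure; 60 s sits well above trigger
cadence and well below typical revisit intervals. An observation's duration
is last frame − first frame, so a single-frame observation has duration
zero — it counts toward attendance and observation tallies but contributes
no feeding time. Two species photographed in alternation at one carcass
form independent, possibly overlapping runs; with one behaviour per frame
there is no precedence rule to define.

## Day/night and activity curves

Sunrise and sunset are computed, not looked up: the NOAA solar calculator
formulation (geometric mean solar longitude and anomaly, equation of
center, apparent longitude, corrected obliquity, then the hour angle at
zenith 90.833°) with a second pass that re-evaluates the equation of time
and declination at the event itself — the drift within a day is worth a few
minutes at shallow high-latitude crossings. Latitudes poleward of 66.5° are
rejected rather than mishandled. Tests hold the implementation within the
minute grid of an independent Meeus-ephemeris minute-scan oracle across UK
latitudes. A user-supplied sunrise/sunset table overrides the computation
when replicating analyses tied to published almanac figures.

The day interval is half-open, [sunrise, sunset): an observation starting
exactly at sunrise is DAY, at sunset NIGHT. An observation's diel class is
that of its start time; bouts spanning sunset are not split. A species with
no observations has an undefined day fraction and is reported missing, not
as 0%.

Activity densities use a wrapped-Gaussian kernel on the 24 h circle —
contributions are summed modulo 24 so mass concentrated near midnight is
not split into two spurious boundary peaks; a plain linear KDE remains
available (`circular=False`) for replicating analyses that ignored the
boundary. `"auto"` bandwidth is the normal reference rule
(1.06 σ n^(−1/5)) on the linearised sample, floored at 0.25 h so a
degenerate sample cannot produce a zero bandwidth; the evaluation grid is
refined to at least four points per kernel standard deviation so the
trapezoid integral holds to 1e−3.

## Attribution model

Let `L` be a carcass's measured loss (its whole initial mass if it was
removed — a carcass carried out of view is assumed fully consumed
elsewhere), `I` its initial mass, and `f̂` the pooled non-vertebrate loss
fraction estimated from caged controls plus experimental carcasses with no
EATING/REMOVING record:

    f̂ = Σ(I − F) / Σ I ,    L_adj = max(0, L − f̂ I)

The floor at zero matters: an unscavenged carcass whose decay happened to
outpace the pooled fraction must not contribute negative vertebrate loss.
The subtraction is applied per carcass by default; a study-wide variant
(subtract `f̂` from the pooled deployed biomass) is available by
configuration because either reading of "adjusted" is defensible.

**Non-removed carcasses.** `L_adj` is allocated in proportion to
`m_i · t_i` (body mass × eating minutes). The two proportionality
assumptions — intake scales with time spent feeding and with scavenger body
mass — are the field's standard; the body-mass factor drops out of the
shares when only one species ate, and the allocation is invariant to
rescaling all body masses. With no eating time recorded, the loss stays
unattributed rather than being forced onto a looker-on.

**Removed carcasses.** The species that carried the carcass off should not
absorb biomass that other species demonstrably ate beforehand. In-situ
eaters are credited at a rate κ (g per kg of scavenger per minute of
eating) calibrated on the non-removed scavenged carcasses by least squares
through the origin, κ = Σ L·S / Σ S² with S = Σ m_i t_i in kg·min, floored
at zero and rescaled downward if the implied in-situ total exceeds `L_adj`;
the remover receives the remainder. This split rule is this package's own
construction — field studies state the proportionality assumptions and the
fully-consumed convention but not the computation for removed carcasses —
so a pure-proportional alternative (remover credited with the entire
adjusted loss) is kept behind `AttributionConfig(removal_rule=
"proportional")`, and neither rule is claimed to be the original. When no
carcass can calibrate κ, the proportional rule is the automatic fallback.

Default body masses (crow 570 g, magpie 230 g, fox 6,500 g) are stand-in
adult values and should be overridden with study-specific estimates.
REMOVING observations contribute no eating minutes; removal credit flows
only through the remover rule.

Per carcass, allocated + unattributed = `L_adj` exactly, and species grams
+ unattributed + non-vertebrate grams reconstruct the measured loss; the
test suite enforces this to 1e−9 g. Scope percentages are kept as raw
floats plus integer display values; a scope's displayed total is the sum of
the displayed species shares, matching how published ledgers are totalled.

## The synthetic-data generator

The simulator emulates the published experimental design: 63 experimental
rat carcasses of 250–300 g (uniform), nine non-woodland urban sites across
three towns with three rooftop (avian-only) sites, ten caged controls,
deployments starting in daytime (11:00 UTC) lasting 48–96 h, spaced so a
site rests ≥ 8 days between uses over a May–September season.

Species parameters printed by the field study are used directly: arrival
latency is Gamma-distributed with mean/SD 683/460 min (crow), 504/436 min
(magpie), 755/278 min (fox) — the Gamma family is the natural choice
because such latencies are modelled with Gamma errors — and day-activity
probabilities are 0.98, 0.996 and 0.092. Non-vertebrate loss averages 9.6%
of initial mass per deployment (SD 0.05 across carcasses, clipped to
[0, 0.5]), accrued linearly in time and stopping early if the carcass is
removed or fully consumed.

Where the field study reports nothing, the defaults are chosen once as
field-plausible and documented here rather than tuned:

* **Attendance** (probability a species finds a given carcass at all):
  crow 0.45, magpie 0.35, fox 0.6 — printed latency statistics are
  conditional on arrival, and attendance in the field was well below 100%.
* **Revisit process**: homogeneous Poisson; mean gaps 240/150/360 min
  (crow/magpie/fox), giving on the order of 25 observations per carcass,
  the magnitude seen in the field.
* **Visit structure**: optional LOOKING (p = 0.3, 5–20 s), EXAMINING
  (10–40 s), then for corvids an EATING bout (p = 0.5 per visit,
  exponential with mean 1.0/0.8 min) at 24 g per kg body mass per minute —
  an intense rate reflecting that camera-recorded eating bouts at small
  carcasses are short and destructive. The fox profile never eats in situ
  (rate 0) and removes with p = 0.08 per visit, corvids with p ≤ 0.004,
  yielding roughly a dozen removals per study, mostly by foxes.
* **Diel placement**: each visit draws day or night by the species'
  day-activity probability and is snapped forward to the next window of
  that state; a visit never crosses a day/night boundary, so a
  0-probability-day species produces no daylight frames at all. The
  snapping rule means the realised first-arrival time (recorded in the
  truth ledger) can be later than the raw Gamma draw.

Eating depletes mass continuously at rate × body mass, capped by what
remains after background loss; a removal takes the entire remainder and
ends the carcass's detection stream. The camera is emulated as one frame
per second of presence — a regular stream standing in for the 0.2 s
trigger / 0.5 s reset cadence of the real hardware, whose exact timing is
not modelled.

What the generator does **not** emulate: non-scavenging vertebrate species
around the carcass, temperature effects on decay (the field study found
none over its narrow range), individual identity or multiple simultaneous
conspecifics, habituation trends across the season, and camera failures or
missed triggers. Passing recovery tests therefore show the estimator is
consistent under the model's own assumptions — proportional intake, shared
corvid consumption rate, clean detection — not that it is unbiased against
every way real data violate them. One known, quantified bias: the
estimator subtracts the full-deployment background fraction from removed
carcasses although their background accrual stopped at removal, deflating
the remover's credit by a few percent; at the study's removal times this
stays within the ±10% recovery bound enforced in the tests.

## Problem sizes and tolerances in the test suite

Recovery tests run the full design (63 carcasses + 10 controls) over 50
seeds for the background-loss fraction (mean within ±0.02 of 0.096), one
200-carcass study for per-species gram recovery (±10% relative), and a
200-carcass nocturnal-fox study for diel recovery (9.2 ± 1.5 percentage
points at ≥ 5,000 observations). Mass conservation is checked to 1e−6 g in
the simulator and 1e−9 g in attribution; KDE normalisation to 1e−3;
sunrise/sunset to ±3 min against a minute-scan ephemeris oracle; and
observation extraction to exact equality against a quadratic reference
grouping on 1,000-frame streams.

## Known limitations

* κ assumes a single shared in-situ consumption rate across species; if
  true rates differ, pre-removal credit on removed carcasses is biased
  toward the faster species (non-removed carcasses are unaffected — their
  allocation uses only relative weights).
* The non-vertebrate fraction is pooled; per-site or per-week variation in
  decay is averaged over.
* No uncertainty intervals are attached to the attribution; the outputs
  are point estimates, as in the ledgers they reproduce.
* Timestamps are handled in UTC throughout; local civil time (BST) only
  matters for presentation and is not applied by the pipeline.
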