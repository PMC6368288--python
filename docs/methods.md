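# Methods

`ecosens` is a desk-scale re-implementation of the sensitivity-analysis
workflow used for end-to-end marine ecosystem models of the Atlantis
family: an age-structured food-web simulator built from the standard
process equations, a one-at-a-time (OAT) parameter perturbation design
with extreme and combination runs, per-run impact-factor scoring, and
additive/non-additive classification of combined perturbations. It is a
tool for studying the *method* — how perturbation designs, impact scoring
and interaction classification behave on a stable multi-trophic system —
not a calibrated model of any real shelf sea.

## Process model

The simulator advances a single well-mixed box with an explicit daily
forward map, in fixed order: forcing → grazing → growth allocation →
grazing losses → mortality → (once per year, on the spawn day) cohort
aging and recruitment. The internal currency is mg N throughout; a single
currency makes the nitrogen-budget tests exact.

**Components.** Invertebrates are biomass pools (one state variable).
Vertebrates carry per-age-class numbers `Num_a`, structural weight and
reserve weight (mg N per individual); biomass is the derived quantity
`Σ_a Num_a (Ws_a + Wr_a)`. The primary producer is prescribed by a
365-day biomass cycle looped every year (constant climate: the bloom
signal is an input, not an output). A detritus pool receives egestion,
mortality, growth overflow and maintenance, and loses mass only through a
linear remineralization/export rate.

**Grazing.** The flux from prey *j* to a predator cohort of biomass B is

    Gr_j = B · C · B*_j / (1 + (C / mum) · Σ_i E · B*_i),

with availability-modified prey biomass
`B*_j = p · δ_overlap · δ_habitat · δ_size · B_j`. The refuge factors δ
default to 1; the gape factor δ_size is a per-prey-age mask. The
denominator uses the predator's maximum specific growth rate, so that as
prey availability grows the assimilated intake `E · Σ Gr` saturates at
`mum · B`. For vertebrate cohorts `mum` is configured as a per-individual
maximum daily mass gain; the engine converts it to a specific rate
`(mum + maintenance · W) / W` so the asymptote covers maintenance plus
maximal growth. Per-prey outflows are capped at the prey's standing
biomass in a step, scaled proportionally across its predators.

**Growth allocation.** Assimilated intake first pays the maintenance cost
(a configured fraction of body mass per day); the surplus becomes
per-individual gain, capped at `mum · dt`, and is split between structural
and reserve weight by a fixed fraction (default 0.6 structural). Under
deficit only the reserve weight shrinks (structural weight is
irreversible); maintenance mass and surplus above the cap are routed to
detritus. Pools gain `min(assimilated, mum · B · dt)`.

**Mortality.** Per age class, `(mL + mQ · Num + mSt) · Num · dt`
individuals are removed (pools use biomass in place of numbers and a
single quadratic coefficient). `mQ` carries separate juvenile and adult
coefficients, split at the maturity age; because the model has no explicit
fishery, fishing pressure is implicitly part of `mQ`. Starvation mortality
`mSt` is a flat extra rate active while the reserve:structural ratio is
below a threshold. Removals are routed to detritus.

**Recruitment** runs once per simulated year at the configured spawn day
(default day 90), immediately after cohort aging (numbers shift one class;
the oldest class is a plus-group merged with number-weighted weights).
Mature age classes whose reserve:structural ratio exceeds the spawn-skip
threshold shed `spawn_fraction · Wr`, forming the spawn mass
`Sp = Σ Num · spawn_fraction · Wr`. Recruits are

* constant mode: `Rc = KDENR ·` (number of mature adults);
* Beverton-Holt mode: `Rc = Sp · BHa / (Biom + BHb)`, optionally times a
  unit-median lognormal deviate `exp(σ z)` drawn once per spawning event
  from the run's seeded generator.

Recruit biomass (`Rc` times the configured recruit weight) is drawn from
the spawn mass — recruitment is capped at `Sp / w0`, and unconverted spawn
mass goes to detritus. This bookkeeping is a deliberate design choice: it
closes the nitrogen budget exactly, at the cost of coupling recruitment to
adult reserve condition somewhat more tightly than the source equations
require. Synthetic webs are generated with at least a 3× margin between
spawn mass and the recruitment target, so the cap binds only in collapsing
stocks.

**Order-of-operation and numerical choices.** dt is 1 day; the explicit
map makes closed-form checks exact (a pool with only linear mortality
follows `B_n = B_0 (1 − mL · dt)^n` to machine precision). Reserve weights
are floored just above zero; mortality fractions are clipped at 1;
non-finite states abort the run naming the step and component. In a closed
web (no producer, no detritus export, σ = 0) total nitrogen is conserved
to ≲1e−15 relative per step; the test suite enforces ≤1e−9 per step over
1000 steps, spanning spawning and aging events.

## Experiment design

The default study perturbs the nine key components (4 zooplankton pools,
3 pelagic fish, 2 top predators) in four parameter families — growth
(`mum`, all age classes together), consumption (`C`), quadratic mortality
(juvenile and adult coefficients together) and recruitment (`BHa` or
`KDENR` by mode; not applicable to pools). All perturbations are
multiplicative. The manifest comprises:

* 1 control run;
* 64 OAT runs: (5 vertebrates × 4 + 4 pools × 3) families × 2 directions
  at ±25%;
* 4 extreme runs: recruitment of the herring-analog ×3.30 and ×0.10,
  growth of the cod-analog ×1.70 and ×0.61;
* 36 combination runs: 8 key-species pairings (one of which pairs an OAT
  run with a two-edit combination, giving three edits) followed by the 28
  unordered pairs of eight selected OAT settings — one high-impact and one
  low-impact setting per parameter family.

The shipped "reference" pairing is an explicit fixture, so manifest
counts are reproducible without simulation; an algorithmic mode derives
the per-family high/low selection from computed OAT impact factors (ties
broken toward the lowest run id) and drops pairs sharing a parameter.

Runs last 55 years at daily steps; metrics use mean biomass over the last
10 years, after a 25-year spin-up.

## Metrics

Per run and component, the signed relative change of window-mean biomass
vs control is categorized by absolute value: <5% weight 1, 5–10% weight
2, 10–20% weight 3, ≥20% weight 4 (bands half-open upward). The **impact
factor** is the mean weight over the scoring scope (all components by
default; a key-species-only scope is available and recorded in the
report). Components with zero control mean are excluded and counted.

For a combination run with parent responses ΔP₁, ΔP₂ and combined
response ΔP₁P₂, the residual `ΔP₁P₂ − (ΔP₁ + ΔP₂)` within ±0.01 is
**additive**; otherwise the response is **synergistic** when
`|ΔP₁P₂| > |ΔP₁ + ΔP₂|` and **antagonistic** when smaller. The ±0.01 band
is symmetric (an absolute-value reading of the defining inequality), and
the classification is invariant under swapping the parents and under
flipping the sign of all three inputs.

## Synthetic webs

`generate_web(template, seed)` builds the default 11-component structure:
a forced producer, small/medium/large/gelatinous zooplankton pools,
capelin-, herring- and polar cod-analogs (Beverton-Holt with lognormal
σ = 0.15), a cod-analog (deterministic Beverton-Holt) and a minke
whale-analog (constant recruitment per adult), plus detritus. Herring
juveniles take capelin recruits through a first-age gape mask. Parameters
are jittered around guild archetypes (weights-at-age ladders with growth
declining with age; geometric survival ladders with accumulating
plus-groups) and then *balanced against the initial state*:

* consumption rates are set to hit a target feeding saturation level
  (95% for vertebrates — food-rich conditions that keep weight ladders on
  schedule; 50% for pools, leaving dynamic range for perturbations);
* availabilities are relaxed where aggregate predator demand would exceed
  a prey's sustainable mortality (70% of the ladder mortality for fish,
  80% of assimilation for pools), shifting demand to other prey;
* linear and quadratic mortality absorb the residual between assimilation
  and losses so every component starts near equilibrium; fish mortality
  carries a 25% buffer because demand-limited predation weakens as a
  stock grows;
* recruitment is calibrated to replace the first age class annually, with
  the Beverton-Holt half-saturation set at 25% of standing biomass so
  compensation is steep.

`stability_check` applies the community rule-of-thumb: post-spin-up
annual-mean biomass must remain within 0.5–1.5 of the first simulated
year for every component (annual means, because the seasonal forcing and
the spawn/aging cycle impose a large uninformative within-year cycle); it
also reports the fraction of vertebrate cohort weights inside the band.
`tune_to_stability` nudges quadratic mortality, recruitment slope and
predator availabilities by bounded factors until a control run passes, or
reports failure explicitly. The shipped fixture
(`ecosens/data/default_web.yaml`) is the tuned seed-1 web and passes the
band on its 55-year control run; this is pinned by a regression test.

What the generator does *not* emulate: spatial structure (the refuge
matrix stands in for polygon overlap), temperature dependence, explicit
fisheries, multi-guild diets of a 50-component system, and observed
Barents Sea time series. Passing tests therefore demonstrate that the
pipeline's bookkeeping, scoring and classification behave correctly on a
stable age-structured web — not that any real ecosystem responds as the
synthetic one does.

## Reproducibility

Every run is a pure function of (configuration, edit list, seed). A study
seed expands into per-run seeds via `SeedSequence([seed, run_index])`, so
any run can be reproduced in isolation; rerunning a study with the same
fixture and seed yields byte-identical report files, independent of the
worker count. Problem sizes used throughout (11 components, ≤8 age
classes, 55-year runs, 105-run studies) are the package's desk-scale
defaults, chosen so a full study completes in minutes on one core.

## Known limitations

* Deep feeding saturation for vertebrates stabilizes weight ladders but
  buffers bottom-up signal propagation: in the shipped webs, zooplankton
  growth perturbations score *lower* median impact than top-predator
  mortality perturbations, the reverse of what full-scale end-to-end
  systems typically show. The comparison is computed and reported by the
  test suite rather than enforced, precisely because it is
  system-dependent.
* The per-age mortality targets of the survival ladder are fitted with one
  linear and two quadratic coefficients per species; residual per-age error
  is absorbed by recruitment compensation, so realized age structure
  deviates mildly from the constructed ladder.
* Producers are prescribed, so grazing on them is an external nitrogen
  inflow; budget tests use closed webs without producers.
* The engine is a daily explicit map; rates are assumed small enough that
  first-order updates are adequate (all default rates are ≤0.3 day⁻¹).
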