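# Methods

## The monitoring problem

Direct observation by researchers is the most accurate way to record
wildlife foraging in crop fields, but it is too labour-intensive for
long-term or multi-site monitoring. Two cheaper data sources exist on
many farms already: motion-triggered camera traps on the field edge and
the crop guards employed to chase animals away, who can log what they
chase. The scientific question this package operationalises is whether
those cheaper streams *predict* the researcher baseline well enough to
stand in for it — answered by regressing period means of the cheap
methods' event counts on the researcher's measures — and, for cameras,
how many units and which positions a design needs.

## Event model

A *crop-foraging event* is one continuous incursion by one species:
it starts when the first individual enters the field and ends when the
last leaves; one minute must pass with the field empty before a new
entry counts as a new event, and co-occurring species are recorded as
separate events. Cameras cannot see the whole field, so their events
are reconstructed from photo times: pooling all retained stations, a
photo opens a new event iff **at least 30 minutes** have passed since
the previous photo of the same species on any camera. The window is
inclusive (a gap of exactly 30:00 separates) and is measured photo to
photo, not event-start to photo. Thirty minutes reflects the field
observation that incursions are rarely longer than that, so photos
closer together most plausibly belong to one visit.

Two consequences of pooled clustering are deliberate and tested:

* event counts are **not monotone** in the number of cameras — an extra
  camera's photo can bridge two otherwise separate events into one;
* per species, the sum of single-camera event counts is always at least
  the pooled count (every pooled event contains at least one photo).

## Matched days and ten-day periods

Methods differ in duty patterns (cameras 24 h daily; guard daily,
06:00–18:00; researchers about five days a week, dawn to dusk), so all
comparisons use *matched days*: the intersection of the three duty
calendars. Zero events on a duty day is data; a non-duty day is
missing. The analysis window (default 2013-05-01 to 2013-08-08, the
overlap of all three methods, 100 days) is cut into consecutive ten-day
periods anchored at its first day; a trailing partial period is
dropped. Per period, species, method and measure, the statistic is the
arithmetic mean over that period's matched days (denominator = number
of matched days, not 10). Camera events are attributed to days by
their start time, and only events starting 06:00–18:00 enter the
method comparison (a flag restores the full 24 h stream). Researcher
events whose crop-item count was not recorded count as events but are
excluded, event-wise, from item sums; the alternative of dropping the
whole day is exposed but not default, since an unmeasured event says
nothing about the other events of that day.

## Agreement regressions

Eight simple OLS fits per study: predictor ∈ {guard, camera} period
mean event rate; response ∈ {researcher crop loss (items/day),
researcher event rate}; species ∈ {baboon, vervet}. Reported columns
are slope, intercept, R², adjusted R² `= 1 − (1−R²)(n−1)/(n−2)`,
residual SE `= sqrt(SSE/(n−2))`, F `= (n−2)R²/(1−R²)` on (1, n−2) df
and its upper-tail p (identical to the slope t-test). n is the number
of periods with at least one matched day. No multiple-testing
correction is applied (the rendered table notes the 8 simultaneous
tests). The closed forms linking R², adj R², F and n let the published
summary table of the originating field study be checked for internal
consistency without its raw data; `cropwatch.reference` carries those
published rows for that purpose only.

## Synthetic data generator

The generator produces the study conditions the analysis assumes, so
every stage is testable without field data. Defaults, chosen once as
field-plausible values and documented here rather than tuned:

| parameter | baboon | vervet | rationale |
|---|---|---|---|
| daily rate (events/day) | 3.0 | 2.0 | a busy focal field; baboons forage more |
| rate amplitude over ten-day blocks | 0.7 | 0.7 | sinusoidal seasonal variation so period means differ and slopes are estimable |
| group size, zero-truncated Poisson λ | 8 | 3 | larger baboon foraging parties |
| duration, Exponential mean (min) | 10 | 10 | P(>30 min) ≈ 5%: events rarely exceed the 30-min window |
| items/individual, Poisson mean | 1.5 | 0.5 | baboons remove more squash |
| guard response probability | 0.85 | 0.15 | the field-observed response rates |
| camera per-passage trigger prob. | 0.9 | 0.4 | smaller-bodied vervets trigger cameras less reliably |

Free (non-species) defaults: guard at 0 m (the southerly corner) with
avoidance weight 2.0 — entry positions are drawn from a density on the
100 m edge proportional to `exp(w·d/L)` with `d` the distance from the
guard, so any positive weight strictly increases the mean distance over
uniform; researcher detection 1.0 with 10% of item counts unrecorded;
researcher duty five days per week (a seeded draw per ISO week); guard
log delay 2 min; burst size 3, 1 s between photos, 5 s rest; 1 min
minimum empty-field gap between same-species truth events.

Mechanics worth noting:

* Daily event counts are Poisson *before* the minimum-gap thinning;
  with 10-min durations the thinning removes only a few percent, and
  tests that check Poisson intervals shorten durations to make it
  negligible.
* Camera trigger opportunities occur as individuals pass the camera
  line: the first individual exactly at the event start, the rest
  spread over the next `passage_spread_seconds`, and — for groups —
  again near the event end as animals exit. A station fires a full
  burst per accepted trigger and cannot re-trigger until
  `trigger + (burst_size−1)·inter_photo + rest` seconds, so inter-burst
  start gaps are always ≥ the rest period.
* Each simulated method consumes its own random stream spawned from the
  master seed; reparameterising one method never changes another's
  draws, and a fixed seed reproduces every table byte for byte.

What the generator does **not** emulate: 2-D movement inside the field,
habituation or deterrence dynamics (detection probabilities are
constant), camera failures, misidentified species, guard transcription
errors, nocturnal foragers, and correlation between group size and
duration. Passing tests therefore show the *pipeline* is correct and
that the regression design recovers known biases under its assumptions;
they do not validate those assumptions against real fields.

## Camera-subset simulation

All combinations of the deployed stations at the requested sizes
(default 1–5; the classic five-camera design gives 5+10+10+5 = 30
subsets below the full set) are re-clustered from scratch on their
restricted photo streams over the full camera deployment window (a flag
restricts to the regression overlap window instead). Summaries report
per-size min/median/max, per-station-alone counts, and the max/min
fold ratio across single cameras per species (flagged undefined when
the minimum is zero).

## Numerical and degenerate-input choices

* Naive local datetimes throughout; days are midnight to midnight.
* Simultaneous photos on two stations are ordered by (timestamp,
  station_id); membership is unaffected because their gap is zero.
* OLS requires n ≥ 3 periods and a non-constant predictor; both are
  hard errors, as are empty matched-day intersections (the error names
  the limiting method) and overlapping same-species researcher events.
* Readers never silently drop rows: malformed rows are rejected with
  line numbers and counted (accepted + rejected = input), out-of-window
  guard times are kept but flagged, and `--strict` promotes rejections
  to errors.
* Missing item counts are `NA`, never 0; merging an `NA` with a known
  count yields `NA`.

## Problem sizes

Tests and the acceptance script run the default 100-day study
(roughly 500 truth events, a few thousand photos), 1000 random
clustering instances of ≤ 200 photos against the independent reference,
and a high-rate season (13 events/day/species, ≥ 1000 truth events per
species) for detection-rate recovery — sizes chosen so the full suite
completes in well under a minute while keeping binomial and Poisson
interval checks tight.
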