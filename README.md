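# cropwatch

Tools for comparing cheap, scalable ways of monitoring wildlife
crop-foraging — motion-triggered camera traps and logs kept by crop
guards — against direct observation by researchers, the costly baseline.
The setting is a 1-ha commercial crop field on the edge of natural
vegetation, foraged by chacma baboons (*Papio ursinus*) and vervet
monkeys (*Chlorocebus pygerythrus*): cameras line the 100 m field edge,
a guard works beside the field by day, and researchers watch from a
hide. The package is for behavioural ecologists and human–wildlife
conflict researchers deciding which monitoring method (and how many
cameras) a study actually needs.

## What it does

1. **Synthetic study generator** — ground-truth incursions (daily
   Poisson counts with seasonal variation, diurnal start times,
   sub-30-min durations, group sizes, per-individual crop-item removal,
   guard-avoiding entry positions) degraded into each method's records:
   camera three-shot bursts with a 5 s post-trigger rest, a guard who
   responds to baboons in 85% of cases but vervets in only 15%, and
   researchers on duty about five days a week, dawn to dusk.
2. **Independent-event delineation** — camera photos are pooled across
   stations and split into independent crop-foraging events wherever at
   least 30 min passed since the previous photo of the same species
   (different species never share an event); observer records merge
   across sub-minute gaps (the "one minute of empty field" rule).
3. **Matched-day, ten-day-period aggregation** — mean daily events and
   crop items per species, method and ten-day period, using only days
   on which *all* methods were recording; events with an unrecorded
   item count still count as events but are excluded from item sums.
4. **Method-agreement regression** — eight simple OLS fits per study:
   {guard, camera} event rates predicting researcher {crop loss, event
   rate} for each species, reported with adjusted R², residual SE, F
   and p, the standard summary columns:

   for simple regression on *n* periods,
   `R² = F / (F + n − 2)` and `adj R² = 1 − (1 − R²)(n − 1)/(n − 2)`,
   with p the upper tail of F(1, n − 2).
5. **Camera-subset design simulation** — for every combination of the
   deployed camera stations (30 subsets of sizes 1–4 for five cameras,
   plus the full set), the photo stream is restricted and re-clustered
   to ask how many events a smaller design *would have* recorded, and
   how strongly the answer depends on camera position relative to the
   guard.

## Worked example

```bash
cropwatch run --config configs/demo.yaml
```

simulates a 100-day season (baboons ~3 incursions/day, vervets ~2,
seed 1), runs every stage and writes CSVs plus a manifest to
`scratch/demo_out/`. The rendered agreement table
(`agreement_summary.txt`) reads:

```
Predictor                             Response                                  Species   Adj. R2  Resid. SE       F       p
----------------------------------------------------------------------------------------------------------------------------
Guard recorded crop-foraging events   Researcher recorded crop loss             Baboons      0.79       6.19   35.30  <.001*
Camera recorded crop-foraging events  Researcher recorded crop loss             Baboons      0.87       4.97   58.98  <.001*
Guard recorded crop-foraging events   Researcher recorded crop-foraging events  Baboons      0.95       0.27  190.06  <.001*
Camera recorded crop-foraging events  Researcher recorded crop-foraging events  Baboons      0.97       0.21  332.67  <.001*
Guard recorded crop-foraging events   Researcher recorded crop loss             Vervets      0.41       1.16    7.27   .027*
Camera recorded crop-foraging events  Researcher recorded crop loss             Vervets      0.76       0.74   29.02  <.001*
Guard recorded crop-foraging events   Researcher recorded crop-foraging events  Vervets      0.62       0.56   15.99   .004*
Camera recorded crop-foraging events  Researcher recorded crop-foraging events  Vervets      0.96       0.19  207.33  <.001*
* p < .05 (8 simultaneous tests, uncorrected)
```

Each row says how well ten-day-period means from a cheap method predict
the researcher baseline: e.g. camera event rates explain most
between-period variance in baboon crop loss (adj R² 0.87), and every
fit's slope is positive because all methods watch the same underlying
incursions. `subset_fold_ratio.csv` reports the contrast between the
best and worst single camera (here 10.8-fold for baboons, 5.8-fold for
vervets): camera placement matters as much as camera count, with the
stations nearest the guard recording the fewest events because animals
enter the field away from the guard.

Individual stages are available as `cropwatch simulate / cluster /
aggregate / agree / subsets / report`, each reading and writing plain
CSV, and as library calls (`cropwatch.MethodAgreement(measures).fit().summary()`).

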