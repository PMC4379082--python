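# uhtape

Design and evaluation of **color-coded uterine-height (UH) tapes** for
identifying preterm-range pregnancies where gestational age (GA) is unknown
and ultrasound is unavailable.

In low-resource settings, birth attendants often cannot determine whether a
pregnancy is in the 24.0–35.6 week window where antenatal corticosteroids
and referral can reduce preterm neonatal mortality. A tri-zone measuring
tape turns symphysis-fundal height — which grows roughly 1 cm per
gestational week — into a literacy-free GA screen: a **yellow** zone read as
GA < 24.0 weeks, a **red** zone read as 24.0–36.0 weeks, and a **green**
zone read as > 36.0 weeks. The zone boundaries are UH percentiles at 24 and
36 completed weeks taken from a population growth chart; the three standard
variants trade sensitivity against specificity:

| tape  | lower boundary (cm) | upper boundary (cm) | character |
|-------|---------------------|---------------------|-----------|
| 10–90 | P10 of UH at 24 w   | P90 of UH at 36 w   | widest red zone, most sensitive |
| 50–50 | P50 at 24 w         | P50 at 36 w         | intermediate |
| 90–10 | P90 at 24 w         | P10 at 36 w         | narrowest red zone, most specific |

This package implements the whole method as a tested library plus CLI:

- `uhtape.synthetic_cohort` — seeded generators for phase-1 paired-operator
  measurement cohorts and phase-2 stratified evaluation cohorts
  (50/10/20/70/100 women across the five GA strata, 250 per site);
- `uhtape.growth_chart` — Bland–Altman operator agreement and per-week
  UH summaries (n, mean, SD, P10, P50, P90) on the mean of the two readings;
- `uhtape.tape_design` — tape construction from a chart and zone
  classification of measurements;
- `uhtape.accuracy` — zone × GA-band cross-tabs, dichotomization for the
  24.0–35.6 endpoint (red = positive) and the 20.0–35.6 endpoint
  (red ∪ yellow = positive), sensitivity/specificity with Wald 95% CIs
  (Clopper–Pearson optional), empirical ROC over the three tape operating
  points with trapezoidal AUC, and prevalence projections;
- `uhtape.paper_data` — the published multi-country evaluation tables
  (4 sites × 3 tapes, 1,029 women) embedded as validated CSV fixtures, so
  the printed results can be recomputed end to end offline.

## Worked example

Simulate both study phases, build the chart, cut the three tapes, and
evaluate them on a fresh 250-woman stratified cohort:

```sh
$ uhtape evaluate --seed 7 --no-plot --outdir demo
10-90 24.0-35.6: sens 97.0% (93.7, 100.0), spec 38.0% (30.2, 45.8)
10-90 20.0-35.6: sens 98.0% (95.8, 100.0), spec 28.0% (19.2, 36.8)
50-50 24.0-35.6: sens 82.0% (74.5, 89.5), spec 78.7% (72.1, 85.2)
50-50 20.0-35.6: sens 89.3% (84.4, 94.3), spec 76.0% (67.6, 84.4)
90-10 24.0-35.6: sens 59.0% (49.4, 68.6), spec 92.0% (87.7, 96.3)
90-10 20.0-35.6: sens 80.0% (73.6, 86.4), spec 90.0% (84.1, 95.9)
AUC 24.0-35.6: 0.86
AUC 20.0-35.6: 0.89
artifacts in demo
```

Each line is one tape × endpoint: the fraction of in-window pregnancies the
tape flags (sensitivity) and the fraction of out-of-window pregnancies it
clears (specificity), with 95% CIs. The nesting of the red zones shows in
the ordering — 10–90 is the most sensitive, 90–10 the most specific — and
both AUCs summarize the three operating points per endpoint. All artifacts
(config, cohorts, chart, tape specs, results) are written under `demo/`
with seed and config hash in every header; rerunning the same config
reproduces them byte for byte.

Recomputing the published evaluation from the embedded cross-tabs:

```sh
$ uhtape reproduce-paper
accuracy: 48/48 cells matched
auc: 5/8 cells matched
projection: 5/5 cells matched
```

All 48 published sensitivity/specificity point estimates *and* their Wald
CIs, and the published 20%-prevalence worked example (25% classified
positive = 16% true preterm + 9% false positive; 71% true term, 4% false
negative), are reproduced exactly at printed rounding. Three of the eight
published AUCs (Zambia, both endpoints; Pakistan, 20.0–35.6) differ by
0.01–0.02 from the trapezoidal area over the published per-tape operating
points; see `docs/methods.md` for the analysis. The command exits non-zero
and names the cells whenever any comparison misses.

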