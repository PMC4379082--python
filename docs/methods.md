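# Methods

## The screening problem and the test

Uterine height (UH, symphysis-fundal distance in cm) rises close to
linearly with gestational age (GA), so a UH cut-off pair can stand in for
GA dating where ultrasound and reliable menstrual dates are missing. A
tri-zone tape encodes two cut-offs as color transitions: yellow (read as
GA < 24.0 weeks), red (24.0–36.0 weeks — the window for antenatal
corticosteroids and referral), green (> 36.0 weeks). The cut-offs are UH
percentiles at 24 and 36 completed weeks from a population growth chart;
the 10–90, 50–50 and 90–10 variants use (P10, P90), (P50, P50) and
(P90, P10) respectively, so their red zones nest and each variant is one
operating point of the same underlying test.

Accuracy is assessed against ultrasound-dated GA (dating scan before 20
weeks) for two endpoint dichotomizations:

* **24.0–35.6 weeks**: cases are pregnancies of 168–251 days; a red
  reading is positive, yellow or green negative.
* **20.0–35.6 weeks**: cases are 140–251 days; red or yellow is positive,
  green negative.

GA is handled in days with half-open bands — "23.6 weeks" means 23 weeks
6 days, so the early band is [140, 168) days, the preterm band [168, 252)
and the term band [252, 287). The last eligible day is 40 weeks 6 days.

## Statistical procedure

**Operator agreement.** Phase-1 cohorts carry two independent readings per
woman. Agreement is summarized Bland–Altman style on op1 − op2: bias =
mean difference, limits of agreement = bias ± 1.96 × sample SD (ddof 1).
The per-woman UH used downstream is the arithmetic mean of the two
readings; missing readings are never imputed.

**Growth chart.** Per completed week (floor of GA days / 7) over weeks
24–36: n, mean, SD, and the P10/P50/P90 of the per-woman mean UH.
Quantiles use linear interpolation between order statistics (numpy's
default); the estimator is exposed as a config option because raw
per-week quantiles at moderate n are sensitive to it. No smoothing or
regression-based percentile curves are fitted — the chart is the raw
per-week summary, which is what physical tape printing consumes.

**Tape construction and classification.** Boundaries are stored at 0.1 cm
resolution (tape printing granularity) and inputs are rounded to 0.1 cm
before comparison, so tie handling is explicit. The default boundary
convention is mid = [lower, upper): a measurement exactly at the lower
boundary reads red (conservative toward referral at the preterm edge),
while one exactly at the upper boundary reads green. The upper-open choice
mirrors the half-open GA bands — 36.0 weeks itself belongs to the term
band — and it makes the noise-free limit exact: with all noise off, UH is
a deterministic step function of completed week and every subject
classifies into the zone of her true GA band, giving 100% sensitivity and
specificity. A fully closed mid zone ([lower, upper]) is available as an
option; under it, noise-free subjects in completed week 36 sit exactly on
the upper boundary and would be read as red. Count-based analyses of
pre-tabulated data are unaffected by the convention.

**Accuracy estimation.** Each cross-tab (3 zones × 3 GA bands) reduces to
a 2×2 per endpoint; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
Binomial 95% CIs are Wald, p ± 1.96·√(p(1−p)/n) — chosen because it is
what the published tables print (verified cell by cell) — clipped to
[0, 1] in the API; the reproduction comparison uses the unclipped form
since published tables print it (one upper limit of 100.5%).
Clopper–Pearson is available as an option. Denominators are always each
tape's own column sums, which correctly handles per-tape missing
measurements (one site × tape combination counts 106 of 107 enrolled term
women).

**ROC/AUC.** Per site and endpoint, the three tapes give three operating
points (1 − specificity, sensitivity), each on its own denominators. The
curve is these points augmented with (0,0) and (1,1), sorted by (fpr,
tpr); the AUC is the trapezoidal area, which for discrete tests equals
the area of the polygon closed onto the x-axis (the test suite checks
this against an independent shoelace implementation). Duplicate-fpr
points contribute zero-width segments in sorted order. The AUC interval
uses the Hanley–McNeil standard error with the mean per-tape case and
non-case counts; it is reported but never asserted against published
values, whose interval method is unknown.

**Prevalence projection.** For a deployment prevalence π, the expected
population mix is TP = π·sens, FN = π·(1−sens), FP = (1−π)·(1−spec),
TN = (1−π)·spec, reported as integer percentages; the four cells sum to
100 before rounding.

## Embedded published tables and the zone-orientation resolution

The four-site evaluation tables (12 zone × GA-band cross-tabs, the
48-cell sensitivity/specificity table with CIs, eight AUCs, enrollment
distributions) ship as plain CSV under `src/uhtape/data/`. The printed
cross-tab labels its outer rows "Yellow" and "Green", but those labels
taken verbatim contradict the printed accuracy table under the stated
decision rules (the "Yellow" rows concentrate in the term band; e.g. one
site × tape would yield a 20.0–35.6 specificity of 0/107 against a
printed 29.9% = 32/107). Interchanging the two outer rows reproduces
every printed sensitivity, specificity and CI exactly, so the fixtures
store semantic labels with the interchange applied: `low` = printed
"Green" row, `mid` = printed "Red" row verbatim, `high` = printed
"Yellow" row. The interchange is recorded on every fixture
(`CrossTab.note`); whether it reflects a table transcription artifact or
the physical color order of the tapes cannot be decided from the printed
text, and no computation relies on color names.

**Reproduction status.** `reproduce_paper()` recomputes 48/48 accuracy
cells with CIs and the 20%-prevalence projection exactly. Five of the
eight published AUCs reproduce at two decimals; Zambia's (both endpoints)
and Pakistan's 20.0–35.6 AUC come out 0.01–0.02 lower (0.64 vs 0.65,
0.70 vs 0.72, 0.82 vs 0.83). The discrepancy is not resolvable from the
published margins: convex-hull areas, per-tape AUC averages and several
axis/orientation variants were all checked and none matches all eight,
while the published per-site values were most plausibly computed from
subject-level readings across the three tapes jointly (an ordinal score),
which the printed per-tape margins cannot reconstruct. The three cells
are reported as mismatches rather than absorbed into a tolerance.

## Synthetic-data generator

The generator emulates the study conditions so every downstream stage is
testable without the undeposited raw data.

* **Growth model**: mean UH at completed week w is `intercept + slope·w`
  with defaults intercept 1.0 cm, slope 0.9 cm/week — 22.6 cm at 24 weeks,
  33.4 cm at 36 weeks, clinically plausible ~1 cm/week growth. Each woman
  deviates by N(0, `between_woman_sd`), default 2.0 cm.
* **Operator error**: independent N(0, `operator_sd`) per reading, default
  0.9 cm so that 95% of inter-operator differences span
  1.96·√2·0.9 ≈ 2.5 cm, inside the 2–3 cm agreement band the tape
  development reported.
* **Phase 1**: a configurable number of women per completed week over
  24–36 (default 40, matching the reported 30–50), GA uniform at day
  resolution within the week (the sampling density within weeks was not
  reported; uniform is an assumption).
* **Phase 2**: stratified targets 50/10/20/70/100 across the bands
  20.0–23.6 / 24.0–27.6 / 28.0–31.6 / 32.0–35.6 / 36.0–40.6 (250 women,
  100 in the preterm band), GA uniform at day resolution within each
  stratum, one masked reading with woman and operator variances added.
* **Determinism**: one `numpy.random.default_rng` seed per simulation
  call; the phase-1 stream draws GA days, then woman effects, then the two
  operator readings; the phase-2 stream is consumed stratum by stratum in
  plan order. The pipeline derives the phase-2 seed as run seed + 1 so the
  two stages are independent but jointly reproducible.

What the generator does **not** model: complication-induced UH reduction
(premature rupture, preeclampsia/IUGR), non-linear early/late growth,
operator bias or site-level measurement style, digit preference, and any
real between-population anthropometric differences — site labels on
synthetic data are bookkeeping only. Passing simulation tests therefore
demonstrates internal consistency of the pipeline under its assumed
linear-Gaussian structure, not field performance of a physical tape.

## Problem sizes and numerical choices

Simulation-based tests use 200–1,000 women per week (parameter-recovery
checks use 1,000, giving a ±0.3 cm band on the week-30 median from the
2.1 cm per-woman SD) and single 250-woman evaluation cohorts; the
fixture-driven reproduction is exact arithmetic on printed counts and
runs in well under a second. The acceptance script's synthetic section
uses the same sizes. Degenerate inputs fail loudly: empty weeks, n < 2
for agreement, zero-case or zero-non-case 2×2 tables, non-positive UH,
and percentile combinations that collapse the mid zone (possible for
90–10 on noisy charts) all raise with the offending quantity named.

## Known limitations

* The published AUC confidence intervals and the original sample-size
  computation use unidentified methods and are out of scope.
* The growth chart is unsmoothed; tapes cut from small phase-1 samples
  inherit week-to-week quantile noise (the 90–10 combination can be
  degenerate on such charts by design).
* The per-week percentile values behind the two physically deployed tape
  families were published only as an image and cannot be asserted here;
  synthetic charts stand in for them.
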