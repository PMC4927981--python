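# Methods

## Problem setting

An F(ab′)₂ therapeutic exposes a hinge neo-epitope when the Fc is cleaved
off, and essentially every cynomolgus monkey (and many humans) carries
preexisting antibodies against that neo-epitope. In a bridging ELISA for
anti-therapeutic antibodies (ATA) this preexisting anti-hinge reactivity
produces a high, animal-specific baseline signal: stable within an animal
over a couple of weeks, but spanning orders of magnitude between animals.
A conventional population cutpoint derived from naive sera is therefore
useless — the assay question is not "is this sample above the naive
population?" but "has this animal's own reactivity changed, and is any
change directed at the drug's CDR?"

The package implements the two-endpoint answer:

1. **Whole-molecule titer endpoint.** Serum is titrated 1/20 then in
   5-fold steps (eight dilutions). The endpoint titer is where the signal
   falls to 2× the mean assay-diluent (blank) absorbance. Each animal gets
   an individual normal-variability band around its own mean predose
   titer, ± 2.33 pooled SDs; posttreatment titers outside the band are
   *increased* or *decreased*.
2. **Anti-CDR endpoint (dual competition).** Each sample is re-assayed at
   1/20 with 50 µg/mL of either a control F(ab′)₂ (same framework and
   hinge, irrelevant CDR; signal *H*) or the drug F(ab′)₂ (signal *D*).
   The control competitor strips anti-hinge and anti-framework binding but
   leaves anti-CDR; the drug competitor strips everything. The **drop
   score** (H − D)/H × 100 % therefore isolates the drug-CDR-specific
   component. Positivity is a one-sided individual cutpoint: baseline mean
   drop score + 2.33 pooled SDs.

## Titer scale and interpolation

Titers live on the log₅ step scale: 0 = endpoint at the 1/20 start
dilution, 1 = 1/100, …, 7 = 1/1 562 500. A 5-fold geometric series makes
log-dilution the natural metric and makes ±k·SD bands symmetric. The
endpoint is located by linear interpolation of raw signal against the
log₅-dilution axis between the first adjacent pair of dilutions that
bracket a downward crossing of the cutpoint; non-monotone curves use
their first crossing.

Known numerical property: near the cutpoint the binding curve decays
approximately exponentially in log-dilution, so the linear chord lies
above the (convex) curve and the interpolated titer overshoots the exact
crossing by at most `max_u [(1−u)/0.8 + ln u / ln 5] ≈ 0.19` log₅ steps
for 5-fold spacing. The overshoot is identical for curves that differ
only by a level shift, so *differences* of titers — the quantity the
classification uses — are unaffected: a noiseless 5-fold concentration
increase moves the measured titer by exactly 1.0 steps. We deliberately
do not fit 4PL/5PL curves; the method is threshold-crossing by design.

Censoring: a sample below the cutpoint already at 1/20 is `below_range`
(sentinel titer 0); one still above the cutpoint at the last dilution is
`above_range` (sentinel 7). Sentinels never enter SD estimation. A
censored posttreatment titer is classified only when its sentinel already
lies outside the band on its own side (e.g. `below_range` with the band
floor above 0 ⇒ *decreased*); otherwise it is *indeterminate*.

## Pooled variability and individual cutpoints

Each animal contributes two pretreatment samples one week apart. Per
animal the sample SD (n−1) is computed on the titer or drop-score scale;
the study-level pooled SD then uses two deliberately distinct
conventions, matching the two endpoints:

* titer endpoint: the **arithmetic mean of per-animal SDs**;
* drop-score endpoint: the **root of the mean per-animal variance (RMS)**.

These differ measurably. For a pair (a, b) with i.i.d. N(µ, σ²) noise the
sample SD is |a−b|/√2, a half-normal variable with mean √(2/π)·σ ≈
0.798 σ — so the mean-of-SDs estimator is biased ~20 % low, while the RMS
estimator is consistent (the per-animal variance is unbiased for σ²).
Both are exposed, tested (including the 0.798 σ bias), and wired to their
respective endpoints; they are not interchangeable.

The cutpoint multiplier defaults to 2.33, the 99th percentile of the
standard normal (exact quantile 2.3263…; the conventional rounded value
is used as the default, and `normal_cutpoint_factor` returns the exact
quantile for any probability). Classification is strict: a value exactly
on a bound is *unchanged*/*negative*.

**Realized null false-positive rate.** The nominal "1 % per side" reading
of 2.33 ignores baseline-mean noise. Under the null, post − mean(2 pre) ~
N(0, 1.5 σ²), so with a consistent pooled SD the realized rates are
2·(1−Φ(2.33·√(2/3))) ≈ 5.7 % two-sided and ≈ 2.9 % one-sided. The package
reports the simulated rate (`null_false_positive_rates`, which uses the
RMS pooling that the closed form assumes) rather than asserting any
nominal figure; with mean-of-SDs pooling the realized titer-endpoint rate
is higher still because the band is ~20 % too narrow.

## Drop-score handling

Negative drop scores (D > H under noise) are retained, not floored at
zero — flooring would bias baseline means and SDs upward. H and D are
replicate means per condition. If either competed signal exceeds the
spectrophotometer accuracy limit (default 3.0 AU, configurable; the
instrument concept has no universal value) the ratio is unreliable and
the sample is *indeterminate*, reported as its own category.

## Synthetic data generator

The generator emulates the features the analysis relies on, with defaults
chosen once as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| background B₀ | 0.05 AU | typical TMB blank |
| S_max | 3.0 AU | uncompeted signals saturate ~3 AU, matching 1.5–3 AU observed plate reads |
| half-saturation K | 1 binding unit | sets the unit scale |
| noise CV | 8 % | typical intra-assay ELISA CV, multiplicative log-normal (mean-preserving) |
| anti-hinge median level | 30 units | gives ~1.85 AU at 1/20 and interpolable titers ~2.8 log₅ steps |
| between-animal log-SD | 1.5 | orders-of-magnitude titer spread between animals |
| within-animal log-SD | 0.15 | week-to-week stability (~0.09 log₅ steps of titer) |
| competitor IC50 | 1 µg/mL (all competed pairs) | ~98 % depletion at the 50 µg/mL in-well concentration |

Competitive depletion is a one-site reversible-inhibition law,
free fraction = 1/(1 + conc/IC50), applied per species × competitor with
the epitope logic fixed by molecule anatomy: the drug F(ab′)₂ competes
hinge, CDR and framework; the control F(ab′)₂ competes hinge and
framework but not CDR; the full-length antibody competes CDR and
framework but not hinge.

Treatment effects are per-dose-group: a responder probability, a
log-normal induced anti-CDR level, and an optional drug-interference
factor that scales all measurable ATA posttreatment (circulating drug
masking ATA). The defaults (5 mg/kg: 80 % responders, median induced
level 20; 15 mg/kg: 60 %, 12, interference 0.8; 50 mg/kg: 50 %, 6,
interference 0.3) qualitatively reproduce the characteristic dose
pattern — titer increases dominating at low dose, decreases at high dose
— without any quantitative claim. Sex is not modeled.

What the generator does **not** emulate: plate/position effects, drift
between runs, heteroscedastic noise at the OD ceiling, hook effects,
matrix interference other than the single multiplicative factor, and
attrition. Passing tests on synthetic data therefore demonstrate the
statistics and plumbing are correct under the stated model, not that the
model captures every feature of real plate reads.

Blank wells are emitted per animal × day with that animal's id so that
the per-animal-day row count is exactly n_dilutions + n_blanks + 2; real
plates would share diluent wells across samples.

## Pipeline conventions

* Replicate wells are averaged per (animal × day × assay × dilution ×
  competitor) before any statistic; the method operates on one signal per
  condition.
* Animals lacking two pretreatment samples for an endpoint are reported
  *unevaluable* for that endpoint; the run continues.
* Animals whose pretreatment titer pair contains a censored value are
  excluded from SD pooling (sentinel arithmetic would contaminate it) but
  keep a cutpoint built from the remaining animals' pooled SD, centered
  on their pretreatment mean.
* Summaries count determinate calls over evaluable animals per group ×
  day; *indeterminate* and *unevaluable* are separate columns, never
  folded into negative.
* The pipeline is a pure function of (config, seed, input): reruns are
  byte-identical, and the run log records config, seed and library
  versions but no timestamps.

## Problem sizes

The default simulated study is 4 groups × 10 animals × 6 sampling days
(2 pre + 4 post), i.e. 2 880 wells; the null false-positive simulation
uses 20 000 animals (the larger size shrinks the Monte Carlo envelope
around the closed-form rates); estimator-recovery checks use 200 paired
baselines. All sizes are package choices mirroring the desk-scale scope
of the method.

## Limitations

* Endpoint titers depend on the interpolation convention; laboratories
  using the "last dilution above cutpoint" step-function convention will
  obtain systematically lower, discretized titers. The classification
  logic is convention-agnostic, but cutpoints must be built and applied
  on the same convention.
* With only two pretreatment samples, the individual center is itself
  noisy; the closed-form null rates above account for this, but a longer
  baseline (or using control-group variation across the whole study)
  would tighten the bands.
* No multiplicity correction across study days is applied, matching the
  method's reporting convention.
* The indeterminate category is terminal; re-assay at further dilution to
  resolve OD-saturated samples is out of scope.
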