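# Methods

## Measurement model

Each service indicator is rated on 12 bipolar adjective-pair items on the
nine-point grid {−4, …, +4}. Items are grouped four per PAD dimension with
alternating orientation; no separate reverse-coding step exists — the
orientation is carried entirely by the signs of the scoring formula
(C4 and C10 reverse pleasure, C2 and C8 reverse arousal, C6 and C12 reverse
dominance). Raw scores are integers; aggregated item means and PAD scores
are real-valued. Because each dimension is a signed mean of four in-range
items, P, A and D always lie in [−4, +4], and scoring is linear: scoring
per respondent and averaging equals averaging items and scoring (the test
suite asserts this to 1 × 10⁻¹²).

Classification is nearest-neighbour in PAD space against 8 benchmark
emotions whose coordinates ship as data (`benchmarks.csv`), not as
constants in logic, so alternative normative tables can be substituted.
Benchmarks coded 01–04 carry positive polarity, 05–08 negative. Exact
distance ties (probability ~0 on real data) are broken toward the lowest
benchmark code and flagged in the result. Distances are computed at full
precision and rounded to 4 decimals only for output formatting.

## Demand rule

Indicator demand is classified from the indicator's mean/SD against its
system part's pooled benchmark. The SD gate is evaluated first: an
indicator at least as dispersed as its part benchmark is a *potential*
demand regardless of its mean; below-benchmark dispersion is split by the
mean into *positive* (above benchmark) and *unactivated* (at or below).
Putting the SD gate first is the only rule consistent with every published
classification: the published potential rows all have means *below* their
benchmark, which a mean-first reading would misclassify. Exact equalities
default to "not greater"/"not less" (configurable via `tie_policy`). The
SD convention is the sample SD (ddof = 1) by default with a population-SD
option; the source aggregates do not state which was used. Demand scores
default to a [1, 5] scale (the published means, 2.31–3.25, fit a 5-point
rating), configurable per cohort spec.

A 10/5/3 split of 18 indicators gives 55.6 / 27.8 / 16.7% at one decimal
half-up. The reference summary prints 55.5 / 27.7 / ≈16.8%, which no
standard rounding of thirds of 18 produces; the package reports the
computed half-up values and footnotes the discrepancy in rendered reports
rather than imitating it.

## Synthetic respondent generator

The generator produces the data the analysis assumes, not a behavioural
model of older adults — only aggregate targets are available to calibrate
against, so the simplest mechanisms matching those aggregates are used.

**PAD cohorts.** Every item's target is the signed latent value of its
dimension, so the signed item mean recovers the latent exactly. Gaussian
item noise (SD `noise_sd`, item-score units) is added, and values are
discretized to the integer grid by *unbiased stochastic rounding*
(floor + Bernoulli of the fractional part), then clipped to ±4.
Deterministic nearest-integer rounding was rejected: it biases every
non-integer latent by up to 0.5 per dimension and can flip the nearest
benchmark even with zero noise (e.g. a latent near (0.38, −0.79, −1.40)
rounds to (0, −1, −1), which is nearer Boredom than its true nearest
benchmark, Reliance). Stochastic rounding keeps the expected score equal to
its target, is exact and deterministic for integer targets at zero noise,
and bounds the worst-case discretization effect by 0.5 per item. Default
cohort size mirrors the 28-respondent study with full item completion;
recovery studies use larger n (200) to separate discretization noise from
classification margins.

**Demand cohorts.** The stochastic model draws i.i.d. from the truncated
normal on the rating scale whose post-truncation mean and SD match the
targets (solved numerically; moment targets infeasible for any distribution
on the scale — `s² ≥ (m−lo)(hi−m)` — raise an error). A `discrete` option
rounds to the integer grid, shifting moments slightly. A deterministic
alternative builds a symmetric two-/three-point design whose sample mean
and ddof-1 SD equal the targets exactly; it is the noiseless calibration
limit used by the recovery experiment.

**Seeding.** One master seed is expanded into per-indicator sub-streams
(seed sequence keyed by a CRC of the indicator code), so simulating a
subset of indicators never changes the draws of the others, and every run
is reproducible bit-for-bit.

**Recovery experiment.** For each noise level and seed, PAD cohorts are
simulated, aggregated and classified; demand cohorts take the
deterministic exact-moment base plus Gaussian score jitter (SD = noise
level, clipped to scale) and run through the full assessment including
benchmark re-estimation. Generating demand categories are defined against
the analytic pooled part benchmark implied by the per-indicator targets —
the exact population quantity the pipeline estimates — so the noiseless
limit recovers 18/18 deterministically. Noise levels within a seed share
the underlying standard-normal draws (common random numbers), which makes
the recovery curves degrade smoothly rather than jitter across the grid.
The default grid (noise SD 0–4, n = 200, 3 seeds) runs in well under a
second.

What the simulator does *not* model: demographic covariates, item-level
factor structure beyond the three dimensions, informative missingness, or
response styles (acquiescence, extreme responding). Passing recovery tests
therefore show the pipeline inverts its own generative assumptions, not
that it is robust to real survey pathologies.

## Numerical and I/O choices

- Percentages are rounded half-up (decimal arithmetic) to 1 decimal;
  distances and PAD values are formatted to 4 decimals on output only.
- CSV readers normalize the typographic minus U+2212 to ASCII `-` before
  parsing, since typeset tables commonly use it.
- Respondents missing any of the 12 items for an indicator are excluded
  from that indicator's aggregation by default (`missing="drop"`); a strict
  mode errors instead. The scoring formula needs all four items per
  dimension, so partial imputation is deliberately not offered.
- Validation rejects (rather than errors on) out-of-range or non-integer
  raw scores, unknown indicator/item codes, and duplicate
  (respondent, indicator, item) triples, keeping the first occurrence and
  reporting per-row reasons.

## Known limitations

- The bundled reference distance matrix used in the test suite contains
  four cells (S_3→Fear, S_11→Relaxation, S_12→Relaxation, S_16→Reliance)
  that are internally inconsistent: the printed value does not equal the
  Euclidean distance between the printed PAD coordinates and the printed
  benchmark, under any rounding chain. The package reproduces the distances
  implied by the PAD coordinates; one end-to-end test that asserts the full
  printed matrix documents and fails on exactly those four cells. No
  tendency (argmin) is affected.
- Whether the reference item means aggregate all respondents or
  per-indicator subsets of familiar users is not stated; the missing-data
  policy supports both readings.
- The adjective pairs behind C1…C12 are treated as abstract coded bipolar
  items; questionnaire rendering and administration are out of scope, as
  are alternative emotion models (circumplex, discrete basic emotions) and
  inferential statistics on demand categories.
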