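# Methods

This note records the models behind `socialrhythms`, the conventions and
numerical choices the implementation commits to, what the synthetic data
does and does not emulate, and the design decisions taken where more than
one reading was defensible.

## Time conventions

Everything runs in fixed-offset UTC+1 wall time with no daylight-saving
adjustment: the corpora the package targets were collected at a fixed
offset, and introducing the late-March DST shift would create a spurious
one-hour discontinuity mid-study. Hours are half-open floor bins
(`[h, h+1)`). Study windows are closed calendar-date ranges; the defaults
are three weeks before (2020-02-17 … 03-08), a discarded two-week
transition (03-09 … 03-22), and the lockdown weeks (03-23 … 04-14). Records
in the transition range or outside all windows are dropped and counted, so
`|before| + |after| + |dropped| = |input|` always holds.

## View-series correction

Cumulative view totals can drop when a platform retracts previously counted
views. The correction redistributes each retraction uniformly over the
recorded prefix: at a drop `T[h+1] < T[h]`, all of `T[0..h]` is multiplied
by `1 − p`, `p = (T[h] − T[h+1])/T[h]`, proceeding chronologically.

Two commitments are worth stating:

* **Multiple drops.** Each correction rescales the already-corrected
  prefix. Because a later drop's two endpoints are never touched by an
  earlier prefix rescaling, the sequential procedure collapses to a closed
  form — entry `j` is multiplied by the product of `min(1, T[h+1]/T[h])`
  over all drops at `h ≥ j` — which is what the vectorized implementation
  computes. The test suite keeps a literal one-pass replay as an
  independent oracle; the two agree to float round-off (checked at
  relative 1e-9), and the output is provably non-decreasing, final-total
  preserving, and idempotent.
* **The first hour.** "The previous hours" is read as the full recorded
  prefix including `T[0]`; leaving `T[0]` fixed (the alternative reading)
  can leave a non-monotone first step and makes a drop at the very first
  gap uncorrectable. The alternative remains available via
  `rescale_first=False`.

Corrected counts are kept as reals; integrality is not preserved and is not
needed downstream.

## Circadian profiles, δ, and the daypart decomposition

Profiles are plain count normalizations; an all-zero table is an error
rather than a NaN profile. For δ, hours with zero activity in *both*
periods are defined as δ = 0 (the natural limit and the only
sign-symmetric choice). δ is antisymmetric in its arguments and bounded in
[−1, 1] by construction.

The night/day × weekend/working decomposition divides pooled cell counts by
their hours of exposure (equivalently hours-per-part × contributing days,
with partial nights at window edges counted pro rata). Night hours after
midnight are attributed to the preceding evening's calendar day — a
Saturday 02:00 event is part of Friday's (working-day) night — on
behavioral-continuity grounds. Rates are pooled over the period rather
than averaged per day; with the exposure bookkeeping the two differ only
at window edges. Cell comparisons use the percent-change convention
`(a − b)/b`.

Default night hours: 23:00–06:00 for tweet-like data, 01:00–08:00 for
view-like data (both 7-hour nights, reflecting the later circadian phase
of passive video watching).

## Hour-content similarity and clustering

`Θ(h₁, h₂)` averages Jaccard similarities of per-day hour sets over days;
days where a cell is empty still count in the normalization (the average is
over days unconditionally), and the empty-vs-anything similarity is 0 —
including empty-vs-empty, so a dead hour reads as "no shared content", not
"identical content". k-means runs on the **rows of Θ** (each hour described
by its similarity to all 24 hours) with 10 restarts and a fixed seed;
labels are canonicalized by first appearance so results are reproducible
verbatim. Default k = 5, matching the five dayparts used by the category
profiles ([0–5], [6–9], [10–14], [15–18], [19–23]); k is exposed
everywhere. A constant Θ is degenerate and yields a single cluster with a
warning rather than an arbitrary partition.

## Lexicon categorization

Tokenization lowercases, strips accents (default on, as wordform matching
against a French-style lexicon should treat é/e alike), and splits on
non-alphanumeric characters. A trailing `*` in a pattern is a prefix
wildcard. An item is assigned, per dimension, to the category with the
strictly largest match count; zero matches or a tie leave it unclassified.
"Similar proportions" is read as an exact tie by default — the only
assumption-free reading — with an optional top-two ratio band
(`tie_ratio`) for stricter unclassification. The global Affect level of an
item is the positive + negative match count.

Fractions are weighted: weight 1 per tweet-like item, hour-resolved view
increments for video-like items (so one video contributes to every bin in
which it was watched — videos are categorized once from title/description
text, but weighted by when the views happened). Within a dimension and
bin, category fractions plus the unclassified fraction sum to 1.

Period comparisons collect per-(day, hour) weighted fractions as the two
samples for a two-sample KS test, one test per category; the result table
carries the per-period means alongside the p-value. Per-(day, hour) cells
(rather than hour-of-day pooled across days) were chosen as the sampling
unit: they are the finest exchangeable unit under the generator and give
the test its sample size.

## Inter-event gaps and the go-to-sleep probability

Gaps are computed between consecutive events of the same user;
zero-duration pairs (identical timestamps) are dropped and counted. Hourly
gap statistics pool all users' gaps by start hour.

The go-to-sleep probability at night hour h is estimated from *qualifying*
gaps starting in h: duration strictly above `min_gap` (default 1 h, to
isolate the last event of a burst) and end not after the close of the
following morning window (default 07:00–12:00). "Following morning" is the
next calendar day for starts at or after noon and the same day for
small-hours starts. The estimate is the fraction of qualifying gaps ending
inside the morning window; the implementation returns the full
decomposition (qualifying + too-short + too-late = total per hour, an
exact identity) and flags hours with no qualifying gaps as NaN. Night
start-hours default to 22:00–04:00 (start hours 22..3 under the floor
convention).

## The synthetic generator

The generator is the package's ground-truth instrument; its defaults *are*
the study conditions the analyses are validated under.

* **Event process.** Per user, day, and hour, counts are Poisson with mean
  `base_rate[h] × weekend_factor(day) × after_factor[h] × awake`, times
  jittered uniformly within the hour (second precision). Hourly
  independence is sufficient because every analysis consumes hourly
  aggregates or gap distributions. Defaults: 500 users; a diurnal base
  rate averaging ≈1.1 events/awake-hour (≈26/day, an active but
  non-professional level); weekend factor 0.9; after-regime factors of
  1.5 on night hours 23–05 and 0.85 on morning hours 6–9.
* **Sleep gating.** Each user draws a nightly bedtime (categorical on a
  noon-anchored hour axis) and a wake hour; no events are emitted in
  between. Bedtime distributions carry a small night-owl tail (mass out to
  05:00) so every night hour retains an awake subpopulation, as in real
  user pools; the after-regime distribution sits about an hour later.
  This model gives the go-to-sleep probability an exactly computable
  ground truth.
* **Content.** Each event plants at most one lexicon category, drawn from
  a per-hour, per-regime categorical built from labeled hour blocks; the
  event's content words (which double as its hashtags) are sampled from
  that category's realized vocabulary, plus neutral filler words. The
  default day has five blocks with distinct dominant categories and a
  lockdown-style thematic drift in the after regime. A helper builds the
  volume-scaled variant (fixed per-category hour shapes, regime-specific
  volume multipliers) whose per-category hour profiles are exactly
  scale-invariant across regimes.
* **Lexicon.** Sixteen categories in the three standard dimensions, six
  mutually disjoint synthetic stems each (four wildcards, two exact
  words); no stem is a prefix of another, so matching on generated text is
  exact by construction.
* **View series.** Each video gets a publish time (hour drawn from the
  diurnal profile), a log-normal popularity, and Poisson hourly increments
  following the wall-clock rate model with a 36 h half-life age decay over
  a 168 h horizon. Corruption: with probability `correction_rate` per
  video-hour, a uniform fraction (5–30%) of all views counted so far is
  retracted, producing a downward jump; the clean series is returned as
  ground truth.
* **Determinism.** One RNG stream seeded from the config; identical
  config + seed gives byte-identical corpora.

**What the generator does not emulate** — and what passing tests therefore
do not certify about real data: realistic language (texts are synthetic
token bags, so tokenizer robustness to real orthography is only covered by
unit tests), per-user activity heterogeneity (optional log-normal
multiplier, off by default), retweet cascades and social-graph structure,
platform censoring or API sampling artifacts, and any coupling between a
user's content and their sleep behavior. Recovery results certify the
*estimators* under the stated stochastic model, not the substantive
findings one would obtain on real corpora.

## Exact expectations as oracles

Every recovery test compares the analysis output against an expectation
computed by direct analysis of the configuration, independent of the
sampling code:

* expected hour profiles and δ from rates × regime factors × the
  steady-state awake probability implied by the sleep categoricals;
* the go-to-sleep curve by numerical integration of the night model on a
  noon-to-noon axis (bedtime/wake categoricals × piecewise-constant
  Poisson rates; grid 1/240 h, discretization error ≪ 0.01): for a gap
  starting at an event in hour h, the next-event time density is
  integrated over the qualifying and sleep-classified regions. The oracle
  assumes a single night type and therefore requires weekend factor 1,
  which the recovery scenario uses.

## Validation scenarios and their sizes

Scenario sizes were chosen so Monte-Carlo standard errors sit well inside
the tolerances being certified:

* δ recovery: 500 users × 21 days/regime, flat 1.1/h base rate (per-hour δ
  SE ≈ 0.006 against a ±0.03 tolerance; the generator's sparsest default
  night hour would put noise at the tolerance itself, defeating the
  purpose of a recovery test). The unnormalized rate-δ isolates the
  planted boost exactly: (1.5−1)/(1.5+1) = 0.2 on night hours, 0 elsewhere.
* Correction oracle: 1000 series × 168 h, ≈8 injected jumps per series.
* Clustering: 20 independently regenerated 6-day corpora; ARI against the
  planted five-block partition.
* KS calibration: 200 replicates of identical 10-day regimes (40 users,
  flat 2.2/h), single all-day content block so the per-(day, hour)
  fraction samples are exchangeable; Poisson-varying cell sizes keep the
  fraction distribution effectively continuous, which the KS p-value
  assumes.
* Sleep recovery: 4000 users × 21 days, flat 1.2/h, bedtimes spread
  22:00–04:00 so every estimator night hour exceeds 5000 qualifying gaps
  (binomial SE ≤ 0.007 against a ±0.05 tolerance).
* Shape resilience: four planted categories with cosine-bump hour shapes
  (floored at 0.25 so no cell starves) and volume multipliers 0.6–1.8
  between regimes. Deviations are standardized per (category, hour) cell;
  since a simultaneous per-cell 3σ rule over 96 cells would fire by chance
  ~25% of the time under the null, the band is Šidák-adjusted to hold the
  family false-alarm rate at the 3σ level (threshold ≈ 4.19). A genuine
  shape change grows as √n and clears any fixed band.

## Known limitations

* The KS comparison inherits the usual caveats of KS tests on weakly
  discrete data; calibration is demonstrated under the generator, not
  proven for arbitrarily sparse categories (rare categories with heavily
  tied zero fractions will test conservatively).
* The go-to-sleep estimator conditions on qualifying gaps; it estimates
  P(sleep | qualifying gap at h), which the oracle mirrors, but which is
  not the unconditional probability of going to sleep after any event.
* Sleep gaps whose morning end falls outside the study window lose their
  closing event and are dropped, slightly deflating night-hour estimates
  near window edges (≈1/n_days relative).
* The daypart decomposition assumes the night attribution rule above;
  corpora where late-night activity belongs behaviorally to the next day
  would need the complementary convention.
* YAML pipeline configs cover the scalar fields and windows; bespoke
  content-block structures are configured programmatically.
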