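# socialrhythms

Circadian analysis of timestamped social-media activity: how does an
exogenous shock — the motivating case is the spring-2020 Covid-19 lockdown —
reshape the daily rhythms of posting and content consumption, the emotional
and thematic content people share, and their sleep, as seen through
inter-event times?

The package is aimed at computational social scientists working with
tweet-like event streams (timestamp, user, text, hashtags) and video-like
view series (hourly cumulative view counts per video). Because such corpora
are usually not redistributable, the package ships a first-class synthetic
generator that emulates their statistical structure — diurnal and weekly
rate cycles, sleep gaps, a regime change that boosts night activity,
hour-dependent category-word mixtures, and retroactive view removals — with
exact ground truth, so every analysis stage can be validated end to end.

## The analyses

All timestamps are fixed-offset UTC+1 wall time; an event at 13:59 belongs
to hour 13. A study is framed as a *before* window, a discarded transition
range, and an *after* window (defaults: Feb 17 – Mar 8, Mar 9 – 22, and
Mar 23 – Apr 14, 2020).

**Circadian profiles.** For each period, the normalized daily activity
profile over clock hours h ∈ {0,…,23}:

    f(h) = Σ_d N(d, h) / Σ_d Σ_h N(d, h)

where N(d, h) counts tweets (or view increments) at hour h of day d. The
per-hour relative change between periods is

    δ(h) = (f_after(h) − f_before(h)) / (f_after(h) + f_before(h)) ∈ [−1, 1].

Activity is also decomposed into night/day × weekend/working-day cells,
normalizing counts by hours-per-part and contributing days, with
post-midnight night hours attributed to the preceding evening's day.

**Hour-content similarity.** With K(d, h) the set of content keys (hashtags,
or ids of videos watched) in day d hour h, the time-similarity matrix

    Θ(h₁, h₂) = (1/N_days) Σ_d J(K(d, h₁), K(d, h₂)),   J = |∩| / |∪|,

is clustered with k-means (rows of Θ as features, default k = 5) to segment
the day into content regimes.

**Lexicon content.** A LIWC-style lexicon (stems with trailing `*`
wildcards; `.dic`, JSON, and TSV dialects) maps words to categories in
three dimensions (General Affects, Specific Emotions, Thematic). Items are
assigned to the strictly prevalent category per dimension (ties and no
matches → unclassified); category prevalence is measured as count-weighted
(tweets) or view-weighted (videos) fractions per period and time bin, and
before/after distributions of per-(day, hour) fractions are compared with
two-sample Kolmogorov–Smirnov tests.

**Inter-event sleep inference.** Per-user gaps between consecutive events
give hourly gap statistics and the go-to-sleep probability: among gaps
starting in a night hour that are longer than 1 h and do not end after the
close of the following morning window (07:00–12:00), the fraction ending
in that window.

**View-series correction.** Platforms occasionally retract views, making
cumulative totals drop; whenever T(h+1) < T(h) the recorded prefix is
rescaled by 1 − p with p = (T(h) − T(h+1)) / T(h), applied chronologically,
yielding a non-decreasing series that preserves the final total.

## Worked example

Simulate a lockdown-style corpus and analyze it:

```bash
socialrhythms simulate --seed 7 --outdir demo_out
# wrote events.jsonl, views.csv, lexicon.json, lexicon.dic, truth.json to
#   demo_out (488952 events, 2000 videos)
socialrhythms analyze --seed 7 --outdir demo_out
# config_hash: b4eb068d9fc05f64
# n_significant_categories_p05: 36
# seed: 7
# sleep_p_mean_after: 0.7897793829617886
# sleep_p_mean_before: 0.8507766501610038
# tweetlike_max_abs_delta: 0.636059409899557
# tweetlike_night_delta_mean: 0.47142850486205645
# viewlike_max_abs_delta: 0.2100343257251961
# viewlike_night_delta_mean: 0.10672122588213664
```

Reading the numbers: the mean night-hour δ is positive on both platforms —
the simulated lockdown shifts activity into the night (the generator's
default regime plants a 1.5× night boost, morning damping, and later
bedtimes, so the analysis should and does recover exactly this signature).
The mean go-to-sleep probability drops from 0.85 before to 0.79 after:
night events are less often the last of the day, i.e. shorter sleep. Most
category/dimension combinations differ significantly between periods
(36 KS tests with p < 0.05) because the default content model also plants a
thematic drift. `demo_out/` then holds the tidy tables: `profiles.csv`,
`profile_delta.csv`, `daypart_rates.csv`, `theta_*.csv`, `hour_clusters.csv`,
`category_ks.csv` (category, avg_before, avg_during, ks_pvalue),
`category_dayparts.csv`, `interevent_stats.csv`, `sleep_probability.csv`,
`summary.json`, and `log.jsonl`. `socialrhythms report` rebuilds
`summary.json` from these intermediates byte-identically.

The same machinery is available as a library — see
`socialrhythms.ingest`, `circadian`, `content_similarity`, `lexicon`,
`interevent`, `synthetic`, `pipeline`.

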