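# Methods

This note records the statistical conventions `emasi` implements, the
decisions taken where more than one convention was defensible, and what the
synthetic generator does and does not emulate.

## The daily SI grid

The analysis substrate is a per-participant calendar-day grid of categorical
SI states (PHQ-9 item-9 scores 0–3, with 0 the resting/modal response).
Surveys are collapsed onto days as follows:

- **Day boundary**: local midnight of the recorded timestamp; no timezone
  conversion (data are assumed recorded in local time at each site).
- **Same-day aggregation**: when several surveys fall on one day the daily
  state is the day's **maximum** item-9 score (conservative for SI
  detection); a `first`-of-day rule is available. SI *instances* are still
  counted per survey, so a same-day pair contributes two instances but one
  elevated day.
- **Grid span**: first to last filled survey. If a boundary survey carries
  no observed item-9 value the grid is trimmed to the first/last day with an
  observed state, so the grid edges are always observed — a requirement of
  the gap-imputation step, which only fills *internal* gaps.
- Days with no survey, or with no item-9 value on any survey, are MISSING.

## Episodes and their durations

An episode starts on a day with state ≥ cutoff (default 1) not already
inside an episode. With the default `bridge_missing=True` it terminates on
the first later day with an **observed 0**, and

    duration_days = termination_day − start_day.

Unobserved days before the terminating 0 are counted, which makes the
duration an upper bound on the true elevated period: the participant may
have returned to rest before the next observation. A run of four elevated
days followed by an observed resting day therefore has duration 4. With
`bridge_missing=False` (sensitivity analysis) a MISSING day ends the run at
the last observed elevated day. Episodes not terminated by an observed 0
before the series ends are **censored**, with duration through the last
elevated day inclusive; they are kept in frequency counts (dropping them
would bias frequency downward) and flagged.

Observed days that are neither 0 nor ≥ cutoff (possible when cutoff > 1)
neither terminate nor extend an episode.

Cohort timescale tables report mean/SD/range/sum/IQR of per-participant
episode frequency and per-participant mean duration, over participants with
at least one episode. IQR uses the linear-interpolation quantile convention;
SD is the sample SD and is undefined (NaN) for a single participant.
Rounding to one decimal happens only at presentation time.

## Analytic-sample selection

Participants enter the analysis when they have at least `min_si_instances`
SI instances (default 2) **and** a daily usage rate at or above their site's
cutoff (defaults 40% / 20% for the two-site design this package targets;
fully configurable). Usage is the fraction of calendar days in the
first-to-last-survey span with ≥ 1 filled mood survey — only the first
survey of a day counts, so duplicates never inflate usage. The exclusion log
records the first criterion that removed each participant.

## Multiple imputation (categorical series)

Gaps are filled **edge-inward**: positions are imputed alternately from the
gap's left and right ends, so every draw can condition on the nearest
available neighbour on both sides. The conditional model is a multinomial
over the observed state space given (a) the nearest left available state,
(b) the nearest right observed state, and (c) log-distance to that right
edge, fitted by pooling all participants' observed transitions via
multinomial logit. Published variants of this edge-recursive scheme differ
in the exact conditioning set; this choice is an approximation documented
here, and a table-only variant (ignoring distance) is what the model falls
back to when the logit fit is degenerate (e.g. complete separation in small
cohorts — the fallback applies additive smoothing with pseudo-count 0.5,
since item-9 scores of 3 are rare). States never observed anywhere are
collapsed into the nearest lower observed category and recorded in the fit
metadata.

`m` (default 10, conventional for moderate missingness) completed datasets
are drawn from independent substreams of one seed; downstream episode
statistics are pooled as **simple means** across imputations, so fractional
pooled counts are expected. Between-imputation variance (Rubin's rules) is
out of scope. Participants with no observable episode on the daily grid are
excluded from episode pooling with a logged reason. After imputation an SI
instance is a day with elevated state — survey multiplicity within a day is
not recoverable from a completed grid.

Guaranteed invariants (tested): observed values are preserved bitwise in
every completed dataset; imputed values stay inside the state space; zero
missingness reproduces the complete-data statistics exactly for any m; and
(inputs, seed, m) fully determine the output.

## PANSS alignment

The **first drop** is the earliest assessment strictly lower than its
immediately preceding assessment (ties are not drops). This reads the
beginning of clinical improvement as a change-point; a baseline-relative
variant (first assessment strictly below the intake score) is available
behind a flag. The lag to SI offset is

    lag_days = date(last SI instance within the PANSS reporting window) − drop_date,

negative when the last SI preceded the drop. Participants lacking two
assessments, a drop, or an in-window instance are excluded **pairwise per
subscale**, so each subscale row can have a different n. Usage–PANSS
correlations are Pearson correlations over pooled (participant, month)
pairs, in both pairing directions (previous-month PANSS vs succeeding-month
usage, and the reverse), with monthly usage computed over the days of that
calendar month inside the participant's reporting span.

## Synthetic cohort generator

The generator exists because the analysis needs realistic inputs with known
truth; it is the simplest process that produces episodic series of the kind
the analysis assumes, not a fitted model of any real cohort.

- **SI process**: a two-state semi-Markov chain on days. From rest an
  episode starts with hazard 0.02/day; episode lengths are geometric with
  mean 2.5 days (discretised gamma available); within-episode severities are
  drawn i.i.d. from (0.60, 0.30, 0.10) over scores {1,2,3}. After the PANSS
  drop plus an offset lag (default 60 days) the onset hazard is multiplied
  by a decay (default 0.35), so SI offset is statistically coupled to
  clinical improvement. Ground-truth episodes are defined on the *realised*
  complete sequence, so adjacent latent episodes that merge into one run
  count once — which keeps the generator consistent with any run-based
  segmenter and slightly inflates realised mean durations above the
  geometric mean.
- **Surveys**: 1–2 per day (70/30), on a per-participant reporting
  probability drawn from 0.40–0.65, minus burst gaps (rate 0.01/day,
  geometric mean length 4 days); together these land daily usage in the
  35–60% range. Timestamps fall in four 6-hour slots with probabilities
  (0.05, 0.45, 0.35, 0.15) — mornings dominate, as in clinic-prompted
  schedules. Items 1–8 are truncated-Poisson draws whose rate rises inside
  episodes, so the PHQ-9 total correlates positively with item 9; every item
  is independently blanked with probability 0.02.
- **PANSS**: monthly assessments; per-subscale baselines are drawn around
  (24, 22, 48) with SD 4 and clipped inside legal ranges; pre-drop scores
  form a non-decreasing plateau, the improvement assessment drops by 3–7
  points, and post-drop scores follow a bounded random walk. The plateau is
  non-decreasing *by construction* so the first strict decrease identifies
  the improvement month exactly — a deliberate idealisation that makes the
  drop month recoverable without noise-induced false change-points. All
  three subscales drop at the same assessment.

Cohort defaults (14 participants, 180–450 day follow-up) target the
summary ranges the analysis is designed around as calibration targets for
fixtures — they are not a claim of reproducing any particular cohort.

**What the generator does not emulate**, hence what passing tests do not
show about real data: missingness is MCAR (day-level and burst); real EMA
missingness is plausibly related to symptom severity (MNAR), which no test
here probes. Survey-level item-9 scores within a day are constant at the
day's state; real within-day fluctuation is absent. PANSS trajectories in
real cohorts can decrease before "true" improvement due to measurement
noise, which the plateau construction deliberately excludes. No passive
sensor streams, no anxiety/sleep surveys, no site-level usage differences
beyond the random per-participant reporting probability.

## Numerical and degenerate-input conventions

- Quantiles: linear interpolation (numpy default).
- Half-open time-slot bins: a survey at exactly 12:00 falls in 12:00–18:00.
  Slot analysis refuses inputs whose timestamps are all midnight (date-only
  exports), since time-of-day is then presumed unrecorded.
- Single-value dispersion statistics are reported as NaN, never 0.
- Pearson/Spearman correlations on constant inputs are flagged undefined
  rather than raised.
- All randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence`; per-participant and per-imputation substreams are spawned
  from the root seed, so outputs are bit-reproducible for a given seed and
  stable under reordering.

## Problem sizes used in the test suite

The bundled recovery checks run on simulated cohorts of 10–100 participants
and 120–365 days — sizes at which the generator's law-of-large-numbers
checks (e.g. mean episode duration within ±10% of the generating 2.5 days
with full observation, ±20% after masking 20% of days and imputing with
m=10) are comfortably stable while the full suite stays fast.

## Known limitations

- Episode durations are day-resolution upper bounds; within-day onset/offset
  ("burst" sampling) is out of scope.
- Severity is only used for instance detection and per-episode maxima; no
  severity-weighted episode scoring.
- Pooling reports means only; no imputation-variance estimates.
- The first-drop marker is a single change-point heuristic, not a remission
  criterion; PANSS total-score analysis is deliberately absent.
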