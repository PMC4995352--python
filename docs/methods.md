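# Methods

## The shifted-cohort half-life statistic

The estimator treats a daily marketplace scrape as a panel of presence
indicators rather than as individual event times. On each observed study day
*s*, the set of apps returned by the keyword search defines a cohort
`B_s`. Its survival series is

    p_s(t) = |{a ∈ B_s : pred(a, s + t − 1)}| / |B_s|,   t = 1, 2, …

where the predicate is membership in the day's search results (*search*
mode) or continued downloadability (*availability* mode — an app counts as
available if it appears in the results or is found by a direct lookup of
its unique identifier). All series are shifted to a common origin and
averaged offset-wise; the half-life is the first reported offset at which
the average `P(t)` falls strictly below 0.5, otherwise the result is
censored ("> span") and the value of `P` at the last reported offset is
quoted as "remaining at end of study".

Assumptions and deliberate properties:

* **Per-day evaluation, no monotone enforcement.** Apps commonly fall out
  of a truncated search window and re-enter as their rank fluctuates, so
  `p_s(t)` may rise. An `absorbing` flag provides the once-gone-always-gone
  variant as a sensitivity analysis; it is never the default.
* **Dominance.** Search presence implies availability, so the
  availability-mode series dominates the search-mode series pointwise for
  every cohort, and the availability half-life can never be the shorter
  one. This is an invariant of the implementation, tested on random panels.
* **Missing days.** A day without data contributes no point at its offset
  in any cohort; values are never carried forward. Day 1 is assumed
  observed (the baseline search defines the study).
* **Support rule.** `P(t)` is reported only where at least `min_series`
  cohorts (default 20) contribute. The rule is applied per offset: late
  offsets are reachable only by early cohorts, and averaging a handful of
  them produces noisy tails that would otherwise move the crossing. The
  alternative reading — keep only cohorts observed for ≥ 20 days — is
  obtainable by filtering the series list before averaging; the per-offset
  rule is the default because it directly limits tail noise.
* **Crossing convention.** Strictly below 0.5, no interpolation, integer
  day offsets with `t = 1` the start day. A curve sitting exactly at 0.5
  has not yet lost half its apps.
* **Cohorts on every observed day.** Including cohorts whose apps first
  appeared mid-study; a day whose search results are empty simply
  contributes no cohort.

`removal_interval(cohorts, span)` converts end-of-study availability into
the headline "one app disappearing every N days": span divided by the total
removals `Σ nᵢ (1 − fᵢ)` over the given cohorts, rounded to one decimal.

## The synthetic marketplace

Real store scrapes cannot be shipped, so validation runs against a
generative stand-in with recorded ground truth. Per day: arrivals are
Poisson(`arrival_rate`); each app is relevant with probability
`relevance_fraction` and faces a constant daily removal hazard (one value
per relevance class; removal is absorbing — the estimator's observable
*search* re-entry arises from ranking churn, not re-listing). Popularity
starts log-normal(`log_mean`, `log_sigma`) and evolves by a multiplicative
log-normal walk (`walk_sigma`); the store ranks alive apps by
affinity × popularity, ties broken lexicographically by app id, and truncates
the visible results to the top `search_window_k`. Reviews arrive
Poisson(`review_rate` × popularity) and score Normal(quality, `score_sigma`)
clipped to [1, 5]; the displayed star rating is the running mean, absent
until the first review. Android panels accumulate Poisson downloads mapped
to the store's banded labels using half-open intervals [50, 100),
[100, 500), … so boundary counts fall in exactly one band. `n_missing_days`
observation days are masked uniformly at random (never day 1) to mimic
collection outages; masking removes observations, not market dynamics.

Defaults emulate the Android "depression" collection: a 246-day span with
35 missing days (211 complete), a 190-result window, a 300-app initial
candidate pool so the day-1 search saturates the window, arrivals at
1.5/day, relevance fraction 0.32, claim fraction 0.38, and removal hazards
0.0017 (relevant) / 0.0007 (non-relevant) back-solved from end-of-study
availability of roughly 66% and 84% under `(1 − h)^245`. The ranking
mechanism, arrival rate and popularity dynamics of the real stores are
unknown; these parameters are plausible stand-ins chosen once, not
estimates, so the simulator supports parameter-recovery and invariance
testing of the estimator — it does not reproduce the real stores' numeric
half-lives, and passing tests say nothing about those values.

What the generator does not emulate: app re-release under a new
identifier, launch-time popularity boosts (available behind a config flag
but off by default), seasonal or weekday effects, category structure,
pricing, and any correlation between popularity and removal hazard beyond
the relevance classes.

Synthetic store descriptions give the claim filter known truth: relevant
apps draw condition-themed templates, non-relevant apps draw keyword-bait
templates (the "great depression" problem), and with probability
`claim_fraction` a relevant app's text embeds one surface form of the claim
vocabulary. Template pools are verified keyword-free, so filter and ground
truth can disagree only through the embedded sentence — on synthetic text,
never.

## Screening

The claim filter tokenizes on non-alphanumeric boundaries and lowercases.
Unstarred keywords match whole tokens only ("clinically" does not match
"clinical"); the two starred entries `effective*` and `evaluate*` match by
prefix; "RCT" matches case-insensitively as a token. Titles are not
searched by default. Relevance is a human judgment: the dual-review merge
takes two complete label maps, requires an explicit resolution for every
disagreement, and refuses to compute proportions while any consensus is
pending. In simulations the registry carries ground-truth reviewer labels
so the pipeline runs unattended.

## Subgroups

Top/bottom subgroups of `size` apps (default 25) are ranked by search rank
(rank 1 is "top"), review count, star rating, or download band (largest is
"top"); apps missing the metric that day are ineligible; ties break by app
id. Membership is re-anchored at each cohort's start day so each averaged
series compares like-for-like snapshots; `freeze_day` selects fixed
membership instead. With only 25 apps per cohort baseline the curves are
noisy by construction, so every output carries its cohort count.

## Numerical and I/O choices

Study days are 1-based integers (day of the first search = 1); a sidecar
JSON manifest records the observed days, the platform, keyword and span, so
"no data that day" is distinct from "no apps that day". Panels are CSV with
a fixed column order and empty fields for absent values; star ratings are
written with Python's shortest round-trip float representation and read
back with round-trip parsing, making write → read → write byte-stable.
Validation rejects offending rows by name — duplicate (day, app) keys, apps
in search but not available, ranks without search presence or duplicated
within a day — and never drops rows silently.

## Problem sizes used in tests

Exact oracle-equivalence checks against a brute-force enumeration use
panels of ≤ 10 apps and ≤ 15 days, where enumeration is trivially
exhaustive. Parameter recovery uses 2000-app, 250-day constant-hazard
marketplaces averaged over 10 seeds (hazard 0.005, so the analytic
availability half-life is ln 2 / 0.005 ≈ 138.6 days, recovered within
10%); the discreteness of the day grid alone biases the crossing upward by
about one day. Dominance is checked on 100 randomly configured small
marketplaces. Monte-Carlo tolerances are three standard errors of the
quantity under test; statistical checks pool several seeds rather than
relying on a single draw.

## Known limitations

The half-life is a property of the *averaged* curve, not a median of
per-app lifetimes, and has no confidence interval here (none is defined for
the published statistic). Cohorts overlap heavily in membership, so their
series are strongly correlated and the support count overstates the
effective sample size. The removal-interval statistic inherits the rounding
of its inputs. The simulator's ranking model is a stand-in; conclusions
about real stores require real panels.
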