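# storeflux

Survival analysis of app-store dynamics from daily keyword-search panels.

Commercial app stores are a volatile distribution channel for health
resources: apps drop out of search results as their popularity falls, and
are withdrawn from sale altogether. For anyone studying a marketplace
longitudinally — clinicians curating app recommendations, reviewers of
mHealth apps, marketplace researchers — the question is *how fast* that
turnover happens. storeflux answers it with two statistics computed from a
daily snapshot panel:

* **search result half-life** — the number of days after which, on average,
  half of the apps returned by a keyword search no longer appear in that
  search's results;
* **app half-life** — the same statistic on continued *download
  availability* (the app can still be found by its unique package/bundle
  identifier), regardless of search visibility.

## The estimator

For each observed study day *s*, the apps in that day's search results form
a cohort with survival series

```
p_s(t) = #{a in cohort_s : a satisfies the mode predicate on day s+t-1} / |cohort_s|
```

with offset *t* = 1 on the start day (so `p_s(1) = 1`). Every cohort is
shifted to a common origin and the series are averaged offset-wise,

```
P(t) = mean over cohorts observed at offset t of p_s(t),
```

reported only where at least `min_series` cohorts contribute (default 20).
The half-life `t_1/2` is the first reported offset with `P(t) < 0.5`;
curves that never cross are censored and reported as "> span" together with
`P` at the last reported offset. Presence is evaluated day by day (apps may
re-enter the search window), missing collection days simply contribute no
observations, and availability dominates search presence pointwise by
construction, so the search half-life can never exceed the app half-life.

Because daily store scrapes cannot be redistributed, the package ships a
ground-truthed synthetic marketplace (`storeflux.simulate`): Poisson app
arrivals, per-class constant removal hazards, a log-normal popularity
random walk ranked into a truncated top-K search window, review/star-rating
accumulation, Android download bands, masked collection days, and store
descriptions with known relevance and effectiveness-claim flags. Constant
hazard *h* implies an availability half-life of `ln 2 / h`, which the
estimator recovers — the core validation.

Also included: the effectiveness-claim keyword pre-screen (exact tokens
plus the starred prefixes `effective*`, `evaluate*`), dual-reviewer
relevance merging with explicit consensus resolution, top/bottom subgroup
analyses by store-visible metrics, and removal-interval arithmetic
("one app disappearing every N days").

## Worked example

```python
from storeflux import (average_series, cohort_series, half_life,
                       panel_from_search_sets, removal_interval)

panel = panel_from_search_sets({1: list("abcd"), 2: list("abc"), 3: list("ab"),
                                4: list("ab"), 5: ["a"], 6: ["a"]})
series = [cohort_series(panel, "search", d) for d in (1, 2)]
curve = average_series(series, min_series=1)
print({t: round(p, 4) for t, p in curve.points.items()})
print(half_life(curve).half_life_days)
print(removal_interval([(197, 0.659), (150, 0.878)], 246))
```

prints

```
{1: 1.0, 2: 0.7083, 3: 0.5833, 4: 0.4167, 5: 0.2917, 6: 0.25}
4
2.9
```

The day-1 cohort {a,b,c,d} decays as [1, .75, .5, .5, .25, .25] and the
day-2 cohort {a,b,c} as [1, 2/3, 2/3, 1/3, 1/3]; their offset-wise average
first drops below 50% at offset 4, so the search result half-life is 4
days. The last line: 246 study days spread over the removals implied by two
platform cohorts (197 apps with 65.9% remaining, 150 with 87.8%) — one
relevant app disappearing every 2.9 days.

## Analysis scripts

`analysis/01_simulate_marketplace.py` … `05_removal_intervals.py` run the
full study pipeline on the synthetic marketplace — simulate, estimate both
half-lives, screen relevance and claims, subgroup analyses, removal
intervals — writing tables under `results/`. The same pipeline is available
as a single configured run via the `storeflux` CLI
(`storeflux run --config pipeline.yaml`, plus `simulate` / `estimate` /
`screen` / `subgroup` subcommands).

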