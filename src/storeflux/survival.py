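"""Shifted-cohort survival estimation of search-result and app half-lives.

The statistic works on daily presence/absence panels rather than individual
event times. For every observed study day *s*, the apps appearing in that
day's keyword search results form a cohort. The cohort's survival series is

    p_s(t) = (# baseline apps satisfying the mode predicate on the day at
              offset t) / |baseline|,        t = 1, 2, ...  (t = 1 is day s)

where the predicate is "still in the search results" (*search* mode) or
"still available to download, whether or not it is in the results"
(*availability* mode). Presence is evaluated day by day — an app may drop
out of the search window and re-enter, so a series need not be monotone.

All cohort series are shifted to a common origin and averaged offset-wise;
an offset is reported only where at least ``min_series`` cohorts contribute
(default 20), which suppresses noisy tail averages supported by few, short
late-study cohorts. The half-life t_1/2 is the first reported offset at
which the averaged proportion falls strictly below 50%; if it never does
within the study span the half-life is censored ("> span") and only the
proportion remaining at the last reported offset is quoted.

Missing observation days contribute no point at their offsets: values are
never carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import CohortError, StorefluxError, UndefinedIntervalError
from .panel import SnapshotPanel

MODES = ("search", "availability")


@dataclass
class SurvivalSeries:
    """One start-day cohort's proportion-remaining trajectory."""

    start_day: int
    mode: str
    baseline: frozenset
    points: dict[int, float]  # offset (1-based) -> proportion in [0, 1]


@dataclass
class AveragedCurve:
    """Offset-wise unweighted mean of shifted cohort series."""

    mode: str
    points: dict[int, float]  # defined only where support >= min_series
    support: dict[int, int]
    min_series: int


@dataclass
class HalfLifeResult:
    """50%-crossing summary of an averaged curve.

    ``half_life_days`` is the first reported offset with proportion < 0.5,
    or ``None`` when censored (the curve never drops below 50% within the
    span). ``remaining_at_end`` is the curve value at the last reported
    offset.
    """

    mode: str
    half_life_days: Optional[int]
    censored: bool
    remaining_at_end: float
    last_offset: int
    n_series: int


class _PanelMatrices:
    """Dense per-app x per-observed-day presence matrices for fast cohorts."""

    def __init__(self, panel: SnapshotPanel) -> None:
        self.days = np.asarray(panel.observed_days, dtype=np.int64)
        self.day_index = {int(d): j for j, d in enumerate(self.days)}
        f = panel.frame
        apps = np.sort(f["app_id"].unique())
        self.apps = apps
        app_index = {a: i for i, a in enumerate(apps)}
        n, m = len(apps), len(self.days)
        self.in_search = np.zeros((n, m), dtype=bool)
        self.available = np.zeros((n, m), dtype=bool)
        if len(f):
            rows = f["app_id"].map(app_index).to_numpy()
            cols = f["date"].map(self.day_index).to_numpy()
            self.in_search[rows, cols] = f["in_search"].to_numpy()
            self.available[rows, cols] = f["available"].to_numpy()

    def mode_matrix(self, mode: str) -> np.ndarray:
        if mode == "search":
            return self.in_search
        if mode == "availability":
            return self.available
        raise StorefluxError(f"unknown mode {mode!r}; expected one of {MODES}")


def cohort_series(
    panel: SnapshotPanel,
    mode: str,
    start_day: int,
    baseline: Optional[frozenset] = None,
    absorbing: bool = False,
    _mats: Optional[_PanelMatrices] = None,
) -> SurvivalSeries:
    """Survival series of the cohort defined by day ``start_day``'s results.

    The baseline is the set of apps in the search results on the start day
    (optionally intersected with ``baseline`` for subgroup analyses). With
    ``absorbing=True`` an app that once fails the predicate is counted as
    gone for all later offsets (a sensitivity analysis; the default follows
    per-day presence).
    """
    mats = _mats or _PanelMatrices(panel)
    if int(start_day) not in mats.day_index:
        raise StorefluxError(f"start_day {start_day} is not an observed day")
    j = mats.day_index[int(start_day)]
    base_mask = mats.in_search[:, j].copy()
    if baseline is not None:
        base_mask &= np.isin(mats.apps, list(baseline))
    n_base = int(base_mask.sum())
    if n_base == 0:
        raise CohortError(f"empty cohort baseline on day {start_day}")
    X = mats.mode_matrix(mode)[base_mask, j:]
    if absorbing:
        X = np.logical_and.accumulate(X, axis=1)
    props = X.sum(axis=0) / n_base
    offsets = mats.days[j:] - int(start_day) + 1
    return SurvivalSeries(
        start_day=int(start_day),
        mode=mode,
        baseline=frozenset(mats.apps[base_mask].tolist()),
        points={int(t): float(p) for t, p in zip(offsets, props)},
    )


def all_cohort_series(
    panel: SnapshotPanel,
    mode: str,
    absorbing: bool = False,
    baseline_per_day=None,
) -> list[SurvivalSeries]:
    """One cohort series per observed day with a non-empty baseline.

    ``baseline_per_day`` optionally maps a start day to an app-id set to
    intersect with that day's results (used by subgroup analyses).
    """
    mats = _PanelMatrices(panel)
    out = []
    for d in mats.days:
        restrict = baseline_per_day(int(d)) if baseline_per_day is not None else None
        try:
            out.append(
                cohort_series(
                    panel, mode, int(d), baseline=restrict, absorbing=absorbing, _mats=mats
                )
            )
        except CohortError:
            continue
    return out


def average_series(series_list: Sequence[SurvivalSeries], min_series: int = 20) -> AveragedCurve:
    """Shift cohorts to a common origin and average offset-wise.

    The mean at each offset is unweighted over the cohorts observed there;
    offsets with fewer than ``min_series`` contributing cohorts are left
    undefined (support counts are still returned for every offset).
    """
    if not series_list:
        raise StorefluxError("average_series requires at least one series")
    if min_series < 1:
        raise StorefluxError("min_series must be >= 1")
    modes = {s.mode for s in series_list}
    if len(modes) > 1:
        raise StorefluxError(f"cannot average mixed modes: {sorted(modes)}")
    max_offset = max(max(s.points) for s in series_list)
    total = np.zeros(max_offset + 1)
    count = np.zeros(max_offset + 1, dtype=np.int64)
    for s in series_list:
        offs = np.fromiter(s.points.keys(), dtype=np.int64, count=len(s.points))
        vals = np.fromiter(s.points.values(), dtype=np.float64, count=len(s.points))
        total[offs] += vals
        count[offs] += 1
    support = {int(t): int(count[t]) for t in range(1, max_offset + 1) if count[t] > 0}
    points = {
        t: float(total[t] / count[t]) for t, c in support.items() if c >= min_series
    }
    return AveragedCurve(mode=modes.pop(), points=points, support=support, min_series=min_series)


def half_life(curve: AveragedCurve) -> HalfLifeResult:
    """Locate the first reported offset where the averaged curve drops
    strictly below 50%, or report censoring with the end-of-study value."""
    if not curve.points:
        raise StorefluxError("curve has no defined offsets")
    offsets = sorted(curve.points)
    crossing = next((t for t in offsets if curve.points[t] < 0.5), None)
    last = offsets[-1]
    return HalfLifeResult(
        mode=curve.mode,
        half_life_days=crossing,
        censored=crossing is None,
        remaining_at_end=float(curve.points[last]),
        last_offset=int(last),
        n_series=int(curve.support.get(1, max(curve.support.values()))),
    )


def estimate_half_life(
    panel: SnapshotPanel,
    mode: str,
    min_series: int = 20,
    absorbing: bool = False,
) -> tuple[AveragedCurve, HalfLifeResult]:
    """Full pipeline: cohorts on every observed day, average, 50%-crossing."""
    series = all_cohort_series(panel, mode, absorbing=absorbing)
    curve = average_series(series, min_series=min_series)
    return curve, half_life(curve)


def removal_interval(
    cohorts: Sequence[tuple[int, float]], span_days: int
) -> float:
    """Days per app removal: span / total removals, to one decimal.

    Each cohort is (number of apps, fraction still remaining at study end);
    removals are summed across cohorts, e.g. across platforms. Raises when
    no removals occurred (the interval is undefined, not infinite).
    """
    if span_days <= 0:
        raise StorefluxError("span_days must be positive")
    removed = 0.0
    for n, frac in cohorts:
        if n <= 0:
            raise StorefluxError("cohort sizes must be positive")
        if not 0.0 <= frac <= 1.0:
            raise StorefluxError("remaining fractions must lie in [0, 1]")
        removed += n * (1.0 - frac)
    if removed == 0.0:
        raise UndefinedIntervalError("no removals observed; interval undefined")
    return round(span_days / removed, 1)
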