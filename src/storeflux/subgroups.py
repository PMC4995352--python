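"""Top/bottom subgroup selection by store-visible metrics and subgroup
half-life estimation.

Subgroups (e.g. the top and bottom 25 apps by search rank, review count,
star rating or download band) probe whether store-visible popularity signals
predict longevity. Membership is, by default, re-anchored at each cohort's
own start day, so every averaged series compares like-for-like snapshots; a
frozen anchor day is available as the alternative reading. Subgroup sizes
are small by construction, so results carry the cohort counts needed to
judge them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import EmptySubgroupError, StorefluxError
from .panel import DOWNLOAD_BUCKETS, SnapshotPanel
from .survival import (
    AveragedCurve,
    HalfLifeResult,
    all_cohort_series,
    average_series,
    half_life,
)

logger = logging.getLogger(__name__)

METRICS = ("rank", "n_reviews", "star_rating", "download_bucket")
_BUCKET_ORDER = {label: i for i, label in enumerate(DOWNLOAD_BUCKETS)}


@dataclass(frozen=True)
class SubgroupSpec:
    """Which apps to keep: the `size` best ("top") or worst ("bottom") by a
    store-visible metric, frozen at ``anchor_day``."""

    metric: str
    which: str
    size: int = 25
    anchor_day: int = 1

    def validate(self, platform: str) -> None:
        if self.metric not in METRICS:
            raise StorefluxError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.which not in ("top", "bottom"):
            raise StorefluxError(f"which must be 'top' or 'bottom', got {self.which!r}")
        if self.size < 1:
            raise StorefluxError("subgroup size must be >= 1")
        if self.metric == "download_bucket" and platform != "android":
            raise StorefluxError("download_bucket subgroups are Android-only")


def select_subgroup(panel: SnapshotPanel, spec: SubgroupSpec) -> frozenset:
    """Apps in the anchor day's search results ranked best/worst by a metric.

    "Top" means rank 1 upward for the rank metric and the largest values for
    the other metrics; apps lacking the metric that day (no rating yet, no
    download band) are ineligible. Ties break lexicographically by app id.
    If fewer than ``size`` apps qualify, all are returned with a warning.
    """
    spec.validate(panel.platform)
    if spec.anchor_day not in set(panel.observed_days):
        raise StorefluxError(f"anchor_day {spec.anchor_day} is not an observed day")
    f = panel.frame
    rows = f[(f["date"] == spec.anchor_day) & f["in_search"]].copy()
    if spec.metric == "rank":
        rows["_key"] = rows["rank"].astype(float)
        ascending = spec.which == "top"  # rank 1 is best
    else:
        if spec.metric == "download_bucket":
            rows["_key"] = rows["download_bucket"].map(_BUCKET_ORDER).astype(float)
        else:
            rows["_key"] = rows[spec.metric].astype(float)
        rows = rows[rows["_key"].notna()]
        ascending = spec.which == "bottom"  # larger values are "top"
    rows = rows[rows["_key"].notna()]
    if rows.empty:
        raise EmptySubgroupError(
            f"no app has metric {spec.metric!r} in the search results of day {spec.anchor_day}"
        )
    rows = rows.sort_values(["_key", "app_id"], ascending=[ascending, True])
    if len(rows) < spec.size:
        logger.warning(
            "subgroup (%s, %s) on day %d has only %d of %d requested apps",
            spec.metric,
            spec.which,
            spec.anchor_day,
            len(rows),
            spec.size,
        )
    return frozenset(rows["app_id"].head(spec.size).tolist())


def subgroup_estimate(
    panel: SnapshotPanel,
    spec: SubgroupSpec,
    mode: str,
    min_series: int = 20,
    absorbing: bool = False,
    freeze_day: Optional[int] = None,
) -> tuple[AveragedCurve, HalfLifeResult]:
    """Averaged curve and half-life with cohort baselines restricted to the
    subgroup.

    By default the subgroup is re-selected at each cohort's own start day
    (``anchor_day`` follows the start day); ``freeze_day`` instead fixes
    membership to the selection made on one day. Cohorts where the
    restriction empties the baseline simply contribute no series.
    """
    if freeze_day is not None:
        frozen = select_subgroup(
            panel, SubgroupSpec(spec.metric, spec.which, spec.size, freeze_day)
        )

        def baseline_per_day(day: int) -> frozenset:
            return frozen

    else:
        cache: dict[int, frozenset] = {}

        def baseline_per_day(day: int) -> frozenset:
            if day not in cache:
                try:
                    cache[day] = select_subgroup(
                        panel, SubgroupSpec(spec.metric, spec.which, spec.size, day)
                    )
                except EmptySubgroupError:
                    cache[day] = frozenset()
            return cache[day]

    series = all_cohort_series(panel, mode, absorbing=absorbing, baseline_per_day=baseline_per_day)
    if not series:
        raise EmptySubgroupError(
            f"subgroup ({spec.metric}, {spec.which}) yields no non-empty cohort"
        )
    curve = average_series(series, min_series=min_series)
    return curve, half_life(curve)


def subgroup_halflife(
    panel: SnapshotPanel,
    spec: SubgroupSpec,
    mode: str,
    min_series: int = 20,
    **kwargs,
) -> HalfLifeResult:
    """Half-life summary for a subgroup (see :func:`subgroup_estimate`)."""
    _, result = subgroup_estimate(panel, spec, mode, min_series=min_series, **kwargs)
    return result
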