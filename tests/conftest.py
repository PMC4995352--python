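"""Shared fixtures: hand-built panels and an independent brute-force oracle.

The oracle recomputes cohort series, shifted averaging and the 50%-crossing
by direct enumeration over (start day, offset) pairs using plain dicts and
loops — deliberately sharing no code with the library implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from storeflux import SnapshotPanel, make_panel
from storeflux.panel import panel_from_search_sets as panel_from_sets


#: Six-day, four-app worked example: the search results shrink from
#: {a,b,c,d} to {a} while every app stays downloadable throughout.
FIXTURE_F_SETS = {
    1: ["a", "b", "c", "d"],
    2: ["a", "b", "c"],
    3: ["a", "b"],
    4: ["a", "b"],
    5: ["a"],
    6: ["a"],
}


@pytest.fixture
def fixture_f() -> SnapshotPanel:
    return panel_from_sets(FIXTURE_F_SETS)


def random_small_panel(seed: int, max_apps: int = 10, max_days: int = 15) -> SnapshotPanel:
    """A random presence panel for oracle-equivalence checks.

    Availability dominates search presence by construction; some days may be
    unobserved (missing), and search sets may be empty.
    """
    rng = np.random.default_rng(seed)
    n_apps = int(rng.integers(2, max_apps + 1))
    span = int(rng.integers(3, max_days + 1))
    apps = [f"a{i:02d}" for i in range(n_apps)]
    observed = [1] + sorted(
        rng.choice(range(2, span + 1), size=int(rng.integers(1, span)), replace=False).tolist()
    ) if span > 1 else [1]
    observed = sorted(set(observed))
    rows = []
    for day in observed:
        avail = [a for a in apps if rng.random() < 0.8]
        searched = [a for a in avail if rng.random() < 0.7]
        rng.shuffle(searched)
        for app in avail:
            rows.append(
                {
                    "date": day,
                    "app_id": app,
                    "platform": "android",
                    "in_search": app in searched,
                    "rank": searched.index(app) + 1 if app in searched else None,
                    "available": True,
                    "version": "1.0",
                    "star_rating": np.nan,
                    "n_reviews": 0,
                    "download_bucket": None,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "date",
            "app_id",
            "platform",
            "in_search",
            "rank",
            "available",
            "version",
            "star_rating",
            "n_reviews",
            "download_bucket",
        ],
    )
    frame["rank"] = frame["rank"].astype("Int64")
    return make_panel(frame, "android", "depression", span, observed)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_cohort(panel: SnapshotPanel, mode: str, start_day: int) -> dict[int, float]:
    """Enumerate one cohort's proportions with plain loops over rows."""
    present = {
        (int(r.date), r.app_id)
        for r in panel.frame.itertuples()
        if (r.in_search if mode == "search" else r.available)
    }
    searched = {(int(r.date), r.app_id) for r in panel.frame.itertuples() if r.in_search}
    baseline = sorted(a for (d, a) in searched if d == start_day)
    assert baseline, "oracle cohort must be non-empty"
    points = {}
    for day in panel.observed_days:
        if day < start_day:
            continue
        offset = day - start_day + 1
        points[offset] = sum((day, a) in present for a in baseline) / len(baseline)
    return points


def brute_average(
    panel: SnapshotPanel, mode: str, min_series: int
) -> tuple[dict[int, float], dict[int, int]]:
    """Average all cohorts offset-wise; returns (points, support)."""
    searched = {(int(r.date), r.app_id) for r in panel.frame.itertuples() if r.in_search}
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for start in panel.observed_days:
        if not any(d == start for (d, a) in searched):
            continue
        for offset, p in brute_cohort(panel, mode, start).items():
            sums[offset] = sums.get(offset, 0.0) + p
            counts[offset] = counts.get(offset, 0) + 1
    points = {t: sums[t] / counts[t] for t in counts if counts[t] >= min_series}
    return points, counts


def brute_half_life(points: dict[int, float]) -> tuple[int | None, float]:
    """(first offset with proportion < 0.5 or None, value at last offset)."""
    offsets = sorted(points)
    crossing = next((t for t in offsets if points[t] < 0.5), None)
    return crossing, points[offsets[-1]]
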