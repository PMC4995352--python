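"""Longitudinal panel and app-registry data model and plain-text I/O.

The central container is the :class:`SnapshotPanel`: one row per (study day,
app) observation of a daily keyword search of an app store, carrying search
presence, rank within the truncated result window, download availability
(established by a per-app fallback search when the app has left the keyword
results), version, star rating, review count and — on Android — a banded
download count.

Days are 1-based integer study-day indices: the day of the first search is
day 1. Days on which no data were collected are simply absent from
``observed_days``; a day with observations but an empty search result set is
therefore distinguishable from a day with no data at all.

On-disk formats are deliberately plain text: the panel is a CSV with a fixed
column order and empty fields for absent values, plus a small JSON sidecar
(``<panel>.meta.json``) holding the platform, keyword, calendar span and the
manifest of observed days. The registry is JSON-lines, one app per line.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

PLATFORMS = ("android", "ios")

#: Fixed panel CSV column order.
PANEL_COLUMNS = (
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
)

#: Android download bands, ordered. Boundaries are half-open [lo, hi) so a
#: count of exactly 100 falls in "100-500", never in two bands at once.
DOWNLOAD_BUCKETS = (
    "<50",
    "50-100",
    "100-500",
    "500-1000",
    "1000-5000",
    "5000-10000",
    "10000-50000",
    "50000-250000",
    ">250000",
)

_BUCKET_EDGES = np.array([50, 100, 500, 1000, 5000, 10000, 50000, 250000])


def download_bucket(n_downloads: int) -> str:
    """Map a cumulative download count to its Android store band."""
    if n_downloads < 0:
        raise ValueError("download count must be nonnegative")
    return DOWNLOAD_BUCKETS[int(np.searchsorted(_BUCKET_EDGES, n_downloads, side="right"))]


@dataclass
class AppRecord:
    """Static metadata for one app, keyed by its store-unique identifier.

    The identifier (package name on Android, bundle id on iOS) is constant
    across renames, so ``names`` is a date-ordered history of display names.
    """

    app_id: str
    platform: str
    names: list[tuple[int, str]] = field(default_factory=list)
    description: str = ""
    reviewer_labels: Optional[tuple[bool, bool]] = None
    consensus_relevant: Optional[bool] = None
    claim_match: Optional[bool] = None
    claim_keywords: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.app_id:
            raise IntegrityError("app_id must be non-empty")
        if self.platform not in PLATFORMS:
            raise IntegrityError(f"unknown platform {self.platform!r}")
        if list(self.names) != sorted(self.names, key=lambda p: p[0]):
            raise IntegrityError(f"names of {self.app_id} not ordered by date")


class AppRegistry:
    """A collection of :class:`AppRecord` with unique ``app_id`` keys."""

    def __init__(self, records: Iterable[AppRecord] = ()) -> None:
        self._apps: dict[str, AppRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: AppRecord) -> None:
        if rec.app_id in self._apps:
            raise IntegrityError(f"duplicate app_id {rec.app_id!r} in registry")
        self._apps[rec.app_id] = rec

    def __getitem__(self, app_id: str) -> AppRecord:
        return self._apps[app_id]

    def __contains__(self, app_id: str) -> bool:
        return app_id in self._apps

    def __len__(self) -> int:
        return len(self._apps)

    def __iter__(self):
        return iter(self._apps.values())

    @property
    def app_ids(self) -> list[str]:
        return list(self._apps)


@dataclass
class SnapshotPanel:
    """The longitudinal observation table plus its collection metadata.

    ``frame`` holds one row per (date, app_id) with the columns of
    :data:`PANEL_COLUMNS`; ``observed_days`` is the manifest of study days on
    which data were actually collected, and ``span_days`` the full calendar
    span, so missing days are explicit.
    """

    frame: pd.DataFrame
    platform: str
    keyword: str
    span_days: int
    observed_days: list[int]

    def __post_init__(self) -> None:
        self.observed_days = sorted(int(d) for d in self.observed_days)


def observed_days(panel: SnapshotPanel) -> list[int]:
    """Return the study days with data, ascending."""
    return list(panel.observed_days)


def make_panel(
    frame: pd.DataFrame,
    platform: str,
    keyword: str,
    span_days: int,
    observed: Sequence[int],
    validate: bool = True,
) -> SnapshotPanel:
    """Normalize dtypes, construct and (by default) validate a panel."""
    frame = _normalize_frame(frame)
    panel = SnapshotPanel(frame, platform, keyword, int(span_days), list(observed))
    if validate:
        validate_panel(panel)
    return panel


def _normalize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"panel is missing column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(PANEL_COLUMNS)].copy()
    frame["date"] = frame["date"].astype(np.int64)
    frame["app_id"] = frame["app_id"].astype(str)
    frame["platform"] = frame["platform"].astype(str)
    for col in ("in_search", "available"):
        if frame[col].dtype != bool:
            frame[col] = (
                frame[col].map(_parse_bool) if frame[col].dtype == object else frame[col].astype(bool)
            )
    frame["rank"] = frame["rank"].astype("Int64")
    frame["version"] = frame["version"].fillna("").astype(str)
    frame["star_rating"] = frame["star_rating"].astype(np.float64)
    frame["n_reviews"] = frame["n_reviews"].fillna(0).astype(np.int64)
    frame["download_bucket"] = frame["download_bucket"].astype(object).where(
        frame["download_bucket"].notna(), None
    )
    return frame.reset_index(drop=True)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise SchemaError(f"cannot parse boolean field value {value!r}")


def validate_panel(panel: SnapshotPanel) -> None:
    """Check every stated panel invariant; raise on the first violation.

    Violating rows are rejected with an error naming them — never silently
    dropped.
    """
    f = panel.frame
    if panel.platform not in PLATFORMS:
        raise SchemaError(f"unknown platform {panel.platform!r}")
    if panel.span_days < 1:
        raise IntegrityError("span_days must be positive")

    obs = set(panel.observed_days)
    if obs and (min(obs) < 1 or max(obs) > panel.span_days):
        raise IntegrityError("observed_days must lie within 1..span_days")

    dup = f.duplicated(subset=["date", "app_id"])
    if dup.any():
        pairs = f.loc[dup, ["date", "app_id"]].itertuples(index=False)
        listing = ", ".join(f"(day {d}, {a!r})" for d, a in pairs)
        raise IntegrityError(f"duplicate (date, app_id) observation(s): {listing}")

    bad_day = ~f["date"].isin(list(obs))
    if bad_day.any():
        days = sorted(f.loc[bad_day, "date"].unique())
        raise IntegrityError(f"observations on unobserved day(s): {days}")

    ghost = f["in_search"] & ~f["available"]
    if ghost.any():
        apps = f.loc[ghost, "app_id"].tolist()
        raise IntegrityError(
            f"in_search=true with available=false (apps in search results are downloadable): {apps}"
        )

    rank_mismatch = f["rank"].notna() != f["in_search"]
    if rank_mismatch.any():
        apps = f.loc[rank_mismatch, ["date", "app_id"]].itertuples(index=False)
        listing = ", ".join(f"(day {d}, {a!r})" for d, a in apps)
        raise IntegrityError(f"rank must be present iff in_search: {listing}")

    ranked = f[f["rank"].notna()]
    if len(ranked):
        if (ranked["rank"] < 1).any():
            raise IntegrityError("ranks must be positive")
        dup_rank = ranked.duplicated(subset=["date", "rank"])
        if dup_rank.any():
            days = sorted(ranked.loc[dup_rank, "date"].unique())
            raise IntegrityError(f"duplicate ranks within a day's results: days {days}")

    rated = f["star_rating"].dropna()
    if len(rated) and ((rated < 1) | (rated > 5)).any():
        raise IntegrityError("star_rating must lie in [1, 5]")
    if (f["n_reviews"] < 0).any():
        raise IntegrityError("n_reviews must be nonnegative")

    has_bucket = f["download_bucket"].notna()
    if panel.platform != "android" and has_bucket.any():
        raise IntegrityError("download_bucket is Android-only")
    bad_bucket = has_bucket & ~f["download_bucket"].isin(DOWNLOAD_BUCKETS)
    if bad_bucket.any():
        labels = sorted(set(f.loc[bad_bucket, "download_bucket"]))
        raise IntegrityError(f"unknown download bucket label(s): {labels}")

    wrong_platform = f["platform"] != panel.platform
    if wrong_platform.any():
        raise IntegrityError("rows with a platform different from the panel's")


def panel_from_search_sets(
    search_sets: dict,
    available_sets: Optional[dict] = None,
    platform: str = "android",
    keyword: str = "depression",
    span_days: Optional[int] = None,
) -> SnapshotPanel:
    """Convenience constructor from per-day search-result lists.

    ``search_sets`` maps a study day to the ordered list of app ids in that
    day's results (rank = list position). ``available_sets`` maps days to
    the apps downloadable that day; by default every app ever seen stays
    available on every observed day, i.e. apps leave the search results but
    not the store. Handy for worked examples and tests.
    """
    all_apps = sorted({a for apps in search_sets.values() for a in apps})
    if available_sets is None:
        available_sets = {d: all_apps for d in search_sets}
    rows = []
    for day in sorted(search_sets):
        in_search = list(search_sets[day])
        for app in sorted(set(in_search) | set(available_sets.get(day, []))):
            searched = app in in_search
            rows.append(
                {
                    "date": day,
                    "app_id": app,
                    "platform": platform,
                    "in_search": searched,
                    "rank": in_search.index(app) + 1 if searched else None,
                    "available": True,
                    "version": "1.0",
                    "star_rating": np.nan,
                    "n_reviews": 0,
                    "download_bucket": None,
                }
            )
    frame = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    frame["rank"] = frame["rank"].astype("Int64")
    observed = sorted(search_sets)
    return make_panel(frame, platform, keyword, span_days or max(observed), observed)


def _meta_path(path: str) -> str:
    return str(path) + ".meta.json"


def write_panel(panel: SnapshotPanel, path: str) -> None:
    """Write the panel CSV and its JSON metadata sidecar.

    Absent values are encoded as empty fields; booleans as ``true``/``false``;
    star ratings with Python's shortest round-trip float representation, so a
    write→read→write cycle is byte-stable.
    """
    validate_panel(panel)
    f = panel.frame
    out = pd.DataFrame(
        {
            "date": f["date"].astype(str),
            "app_id": f["app_id"],
            "platform": f["platform"],
            "in_search": np.where(f["in_search"], "true", "false"),
            "rank": f["rank"].map(lambda r: "" if pd.isna(r) else str(int(r))),
            "available": np.where(f["available"], "true", "false"),
            "version": f["version"],
            "star_rating": f["star_rating"].map(lambda x: "" if pd.isna(x) else repr(float(x))),
            "n_reviews": f["n_reviews"].astype(str),
            "download_bucket": f["download_bucket"].map(lambda b: "" if b is None else b),
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")
    meta = {
        "platform": panel.platform,
        "keyword": panel.keyword,
        "span_days": panel.span_days,
        "observed_days": panel.observed_days,
    }
    with open(_meta_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_panel(path: str, validate: bool = True) -> SnapshotPanel:
    """Read a panel CSV (and its sidecar metadata, if present) and validate.

    Without a sidecar the observed days are inferred from the data and the
    span from the largest observed day.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path,
        dtype={
            "date": np.int64,
            "app_id": str,
            "platform": str,
            "in_search": str,
            "rank": "Int64",
            "available": str,
            "version": str,
            "star_rating": np.float64,
            "n_reviews": np.int64,
            "download_bucket": str,
        },
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in PANEL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"panel file {path} is missing column(s): {', '.join(missing)}")
    meta_path = _meta_path(path)
    if os.path.exists(meta_path):
        with open(meta_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        platform, keyword = meta["platform"], meta["keyword"]
        span, observed = int(meta["span_days"]), meta["observed_days"]
    else:
        observed = sorted(raw["date"].unique().tolist()) if len(raw) else []
        span = max(observed) if observed else 1
        platform = raw["platform"].iloc[0] if len(raw) else "android"
        keyword = ""
    return make_panel(raw, platform, keyword, span, observed, validate=validate)


def write_registry(registry: AppRegistry, path: str) -> None:
    """Write the registry as JSON-lines, one app object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in registry:
            obj = {
                "app_id": rec.app_id,
                "platform": rec.platform,
                "names": [[d, n] for d, n in rec.names],
                "description": rec.description,
                "reviewer_labels": list(rec.reviewer_labels) if rec.reviewer_labels else None,
                "consensus_relevant": rec.consensus_relevant,
                "claim_match": rec.claim_match,
                "claim_keywords": rec.claim_keywords,
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_registry(path: str) -> AppRegistry:
    """Read a JSON-lines registry written by :func:`write_registry`."""
    registry = AppRegistry()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            labels = obj.get("reviewer_labels")
            registry.add(
                AppRecord(
                    app_id=obj["app_id"],
                    platform=obj["platform"],
                    names=[(int(d), n) for d, n in obj.get("names", [])],
                    description=obj.get("description", ""),
                    reviewer_labels=tuple(labels) if labels else None,
                    consensus_relevant=obj.get("consensus_relevant"),
                    claim_match=obj.get("claim_match"),
                    claim_keywords=list(obj.get("claim_keywords", [])),
                )
            )
    return registry
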