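"""Synthetic app-store marketplace with known ground truth.

The study data this package analyses were daily keyword-search scrapes of
the Google Play and iTunes stores; no such scrape is redistributable here,
so this module generates panels with the same statistical structure and a
recorded ground truth, enabling parameter-recovery tests of the estimator.

Generative model, per simulated day:

* Apps arrive as a Poisson process (``arrival_rate`` per day) on top of
  ``n_initial_apps`` present at day 1.
* Each app is clinically relevant with probability ``relevance_fraction``
  and faces a constant daily removal hazard (settable separately per
  relevance class). Removal is absorbing: a removed app never re-lists.
* Latent popularity starts log-normal and follows a multiplicative
  log-normal random walk; the store ranks alive apps by
  ``keyword affinity x popularity`` and exposes only the top
  ``search_window_k`` in the keyword search results — apps below the cutoff
  remain downloadable but invisible to the search, which is exactly the
  distinction between the two survival modes the estimator measures.
* Reviews arrive Poisson with rate proportional to popularity; each review
  scores Normal(true quality, sigma) clipped to [1, 5], and the star rating
  shown is the running mean. Android panels additionally accumulate
  downloads, reported only as the store's banded counts.
* A configurable number of days is masked (uniformly, never day 1) to mimic
  collection outages.

Identical config and seed give a byte-identical panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, StorefluxError
from .panel import (
    AppRecord,
    AppRegistry,
    SnapshotPanel,
    _BUCKET_EDGES,
    DOWNLOAD_BUCKETS,
    make_panel,
)


@dataclass(frozen=True)
class PopularityModel:
    """Log-normal initial popularity and daily multiplicative random walk."""

    log_mean: float = 0.0
    log_sigma: float = 1.0
    walk_sigma: float = 0.08
    launch_boost: float = 1.0  # multiplier applied to new arrivals' initial draw


@dataclass(frozen=True)
class RatingModel:
    """True quality, review arrival and review-score noise parameters."""

    quality_low: float = 2.5
    quality_high: float = 4.8
    review_rate: float = 0.2  # expected reviews/day per unit popularity
    score_sigma: float = 0.8
    download_rate: float = 5.0  # expected downloads/day per unit popularity (Android)


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one marketplace run.

    Defaults emulate the Android "depression" collection conditions: a
    246-day span with 35 missing observation days, a 190-result search
    window saturated on day 1, and removal hazards back-solved from the
    end-of-study availability of relevant (65.9%) and non-relevant (83.8%)
    apps under a constant-hazard model.
    """

    n_initial_apps: int = 300
    arrival_rate: float = 1.5
    removal_hazard_relevant: float = 0.0017
    removal_hazard_nonrelevant: float = 0.0007
    relevance_fraction: float = 0.32
    claim_fraction: float = 0.38
    search_window_k: int = 190
    platform: str = "android"
    keyword: str = "depression"
    popularity: PopularityModel = field(default_factory=PopularityModel)
    rating: RatingModel = field(default_factory=RatingModel)
    affinity_sigma: float = 0.5
    version_update_prob: float = 0.01
    span_days: int = 246
    n_missing_days: int = 35
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "removal_hazard_relevant": self.removal_hazard_relevant,
            "removal_hazard_nonrelevant": self.removal_hazard_nonrelevant,
            "relevance_fraction": self.relevance_fraction,
            "claim_fraction": self.claim_fraction,
            "version_update_prob": self.version_update_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        positives = {
            "n_initial_apps": self.n_initial_apps,
            "search_window_k": self.search_window_k,
            "span_days": self.span_days,
        }
        for name, v in positives.items():
            if v < 1:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.arrival_rate < 0:
            raise ConfigError(f"arrival_rate must be nonnegative, got {self.arrival_rate}")
        if not 0 <= self.n_missing_days < self.span_days:
            raise ConfigError(
                f"n_missing_days must lie in [0, span_days), got {self.n_missing_days}"
            )
        if self.platform not in ("android", "ios"):
            raise ConfigError(f"platform must be android or ios, got {self.platform!r}")
        if self.affinity_sigma < 0 or self.popularity.log_sigma < 0 or self.popularity.walk_sigma < 0:
            raise ConfigError("dispersion parameters must be nonnegative")
        if not self.rating.quality_low <= self.rating.quality_high:
            raise ConfigError("rating.quality_low must not exceed rating.quality_high")
        if not (1.0 <= self.rating.quality_low and self.rating.quality_high <= 5.0):
            raise ConfigError("true quality range must lie within [1, 5]")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "popularity" in data and isinstance(data["popularity"], dict):
            data["popularity"] = PopularityModel(**data["popularity"])
        if "rating" in data and isinstance(data["rating"], dict):
            data["rating"] = RatingModel(**data["rating"])
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Latent state of a simulated marketplace.

    ``table`` has one row per app: relevance, claim flag (set once
    descriptions are generated), arrival day and removal day (``NaN`` for
    never-removed). ``popularity`` is the full apps x days latent
    trajectory, aligned with ``table`` rows.
    """

    table: pd.DataFrame
    popularity: np.ndarray

    def removal_day(self, app_id: str) -> Optional[int]:
        row = self.table.loc[self.table["app_id"] == app_id, "removal_day"]
        if row.empty or pd.isna(row.iloc[0]):
            return None
        return int(row.iloc[0])


# Surface forms of the effectiveness-claim vocabulary embedded in synthetic
# descriptions; "effectiveness" and "evaluated" exercise the prefix rules.
CLAIM_SURFACE_FORMS = (
    "effective",
    "effectiveness",
    "clinical",
    "study",
    "studies",
    "proven",
    "proof",
    "evaluated",
    "tested",
    "guaranteed",
    "evidence",
    "RCT",
    "trial",
)

# Base templates are deliberately free of claim-keyword tokens so the
# ground-truth claim flag and the keyword filter can only agree.
RELEVANT_TEMPLATES = (
    "Track your mood and manage depression symptoms with daily check-ins.",
    "Cognitive behavioural exercises and thought diaries for depression and low mood.",
    "A daily journal to monitor depressive symptoms, sleep and energy.",
    "Guided relaxation and breathing support for people living with depression.",
    "Self-help modules and mood charts for depression management.",
)

NONRELEVANT_TEMPLATES = (
    "Explore the history of the Great Depression with interactive timelines.",
    "Dark and moody wallpaper pack for your home screen.",
    "Weather charts for tracking atmospheric depressions and storm fronts.",
    "Relaxing piano melodies for winding down in the evening.",
    "A trivia quiz about economics through the decades.",
)

CLAIM_SENTENCE = "Users and reviewers describe the approach as {kw} for low mood."


def simulate_marketplace(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[SnapshotPanel, AppRegistry, GroundTruth]:
    """Run the birth-death marketplace and return panel, registry and truth.

    ``seed`` overrides ``config.seed`` when given. The returned registry
    already carries synthetic descriptions (see
    :func:`generate_descriptions`) and ground-truth reviewer labels, so the
    full screening pipeline can run unattended.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    span = config.span_days

    # --- births ---------------------------------------------------------
    arrivals_per_day = rng.poisson(config.arrival_rate, size=span - 1) if span > 1 else np.array([], int)
    arrival_days = np.concatenate(
        [np.ones(config.n_initial_apps, dtype=np.int64)]
        + [np.full(k, d, dtype=np.int64) for d, k in enumerate(arrivals_per_day, start=2)]
    )
    n_apps = len(arrival_days)
    width = max(4, len(str(n_apps)))
    app_ids = np.array([f"app{i:0{width}d}" for i in range(n_apps)])

    # --- latent per-app state -------------------------------------------
    relevant = rng.random(n_apps) < config.relevance_fraction
    hazard = np.where(relevant, config.removal_hazard_relevant, config.removal_hazard_nonrelevant)
    # lifetime in days after arrival; geometric draw, infinite when hazard=0
    u = rng.random(n_apps)
    with np.errstate(divide="ignore"):
        lifetime = np.where(
            hazard > 0, np.ceil(np.log1p(-u) / np.log1p(-np.clip(hazard, 0, 1 - 1e-12))), np.inf
        )
    removal_day = arrival_days + lifetime  # app alive on [arrival, removal)

    pop0 = rng.lognormal(config.popularity.log_mean, config.popularity.log_sigma, n_apps)
    pop0 = np.where(arrival_days > 1, pop0 * config.popularity.launch_boost, pop0)
    walk = np.exp(rng.normal(0.0, config.popularity.walk_sigma, size=(n_apps, span)))
    affinity = rng.lognormal(0.0, config.affinity_sigma, n_apps)
    quality = rng.uniform(config.rating.quality_low, config.rating.quality_high, n_apps)

    popularity = np.zeros((n_apps, span))
    minor_version = np.zeros(n_apps, dtype=np.int64)
    review_count = np.zeros(n_apps, dtype=np.int64)
    review_score_sum = np.zeros(n_apps)
    downloads = np.zeros(n_apps, dtype=np.int64)

    frames = []
    current_pop = pop0.copy()
    for day in range(1, span + 1):
        alive = (arrival_days <= day) & (day < removal_day)
        idx = np.flatnonzero(alive)
        if day > 1:
            current_pop = current_pop * walk[:, day - 1]
        popularity[:, day - 1] = np.where(alive, current_pop, np.nan)

        # accumulate reviews / downloads / version bumps for alive apps
        n_new = rng.poisson(config.rating.review_rate * current_pop[idx])
        total_new = int(n_new.sum())
        if total_new:
            owners = np.repeat(idx, n_new)
            scores = np.clip(rng.normal(quality[owners], config.rating.score_sigma), 1.0, 5.0)
            review_score_sum += np.bincount(owners, weights=scores, minlength=n_apps)
            review_count += np.bincount(owners, minlength=n_apps)
        if config.platform == "android":
            downloads[idx] += rng.poisson(config.rating.download_rate * current_pop[idx])
        bump = rng.random(len(idx)) < config.version_update_prob
        minor_version[idx[bump]] += 1

        if len(idx) == 0:
            continue
        # top-K by affinity x popularity, ties by app_id lexicographic order
        score = affinity[idx] * current_pop[idx]
        order = idx[np.lexsort((app_ids[idx], -score))]
        k = min(config.search_window_k, len(order))
        in_search_ids = order[:k]
        rank = np.full(n_apps, 0, dtype=np.int64)
        rank[in_search_ids] = np.arange(1, k + 1)

        stars = np.where(review_count[idx] > 0, review_score_sum[idx] / np.maximum(review_count[idx], 1), np.nan)
        bucket = (
            np.array(DOWNLOAD_BUCKETS, dtype=object)[
                np.searchsorted(_BUCKET_EDGES, downloads[idx], side="right")
            ]
            if config.platform == "android"
            else np.full(len(idx), None, dtype=object)
        )
        frames.append(
            pd.DataFrame(
                {
                    "date": np.full(len(idx), day, dtype=np.int64),
                    "app_id": app_ids[idx],
                    "platform": config.platform,
                    "in_search": rank[idx] > 0,
                    "rank": pd.array(
                        np.where(rank[idx] > 0, rank[idx], -1), dtype="Int64"
                    ),
                    "available": True,
                    "version": np.char.add("1.", minor_version[idx].astype(str)),
                    "star_rating": stars,
                    "n_reviews": review_count[idx],
                    "download_bucket": bucket,
                }
            )
        )

    frame = pd.concat(frames, ignore_index=True) if frames else _empty_frame()
    frame.loc[frame["rank"] == -1, "rank"] = pd.NA
    panel = make_panel(
        frame, config.platform, config.keyword, span, list(range(1, span + 1)), validate=False
    )

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "app_id": app_ids,
                "relevant": relevant,
                "claim": pd.array([None] * n_apps, dtype="boolean"),
                "arrival_day": arrival_days,
                "removal_day": np.where(np.isinf(removal_day), np.nan, removal_day),
            }
        ),
        popularity=popularity,
    )

    registry = AppRegistry(
        AppRecord(
            app_id=app_ids[i],
            platform=config.platform,
            names=[(int(arrival_days[i]), f"App {app_ids[i][3:]}")],
            reviewer_labels=(bool(relevant[i]), bool(relevant[i])),
            consensus_relevant=bool(relevant[i]),
        )
        for i in range(n_apps)
    )
    desc_seed = int(rng.integers(0, 2**31 - 1))
    generate_descriptions(registry, truth, config, desc_seed)

    if config.n_missing_days:
        mask_seed = int(rng.integers(0, 2**31 - 1))
        panel = mask_missing_days(panel, config.n_missing_days, mask_seed)
    return panel, registry, truth


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": pd.Series(dtype=np.int64),
            "app_id": pd.Series(dtype=str),
            "platform": pd.Series(dtype=str),
            "in_search": pd.Series(dtype=bool),
            "rank": pd.Series(dtype="Int64"),
            "available": pd.Series(dtype=bool),
            "version": pd.Series(dtype=str),
            "star_rating": pd.Series(dtype=np.float64),
            "n_reviews": pd.Series(dtype=np.int64),
            "download_bucket": pd.Series(dtype=object),
        }
    )


def generate_descriptions(
    registry: AppRegistry, truth: GroundTruth, config: SimulationConfig, seed: int
) -> AppRegistry:
    """Attach synthetic store descriptions with known claim ground truth.

    Relevant apps draw a condition-themed template; with probability
    ``claim_fraction`` a sentence embedding one effectiveness-claim keyword
    is appended and the app's ground-truth claim flag is set. Non-relevant
    apps draw keyword-bait templates (the "great depression" problem). Base
    templates contain no claim tokens, so truth and filter can only agree.
    """
    rng = np.random.default_rng(seed)
    claim_flags = {}
    rel_map = dict(zip(truth.table["app_id"], truth.table["relevant"]))
    for rec in registry:
        relevant = bool(rel_map.get(rec.app_id, False))
        if relevant:
            desc = RELEVANT_TEMPLATES[int(rng.integers(len(RELEVANT_TEMPLATES)))]
            has_claim = bool(rng.random() < config.claim_fraction)
            if has_claim:
                kw = CLAIM_SURFACE_FORMS[int(rng.integers(len(CLAIM_SURFACE_FORMS)))]
                desc = desc + " " + CLAIM_SENTENCE.format(kw=kw)
        else:
            desc = NONRELEVANT_TEMPLATES[int(rng.integers(len(NONRELEVANT_TEMPLATES)))]
            has_claim = False
        rec.description = desc
        claim_flags[rec.app_id] = has_claim
    truth.table["claim"] = pd.array(
        [claim_flags.get(a) for a in truth.table["app_id"]], dtype="boolean"
    )
    return registry


def mask_missing_days(panel: SnapshotPanel, n_missing: int, seed: int) -> SnapshotPanel:
    """Drop ``n_missing`` observation days uniformly at random (never day 1).

    The calendar span is unchanged; the masked days simply vanish from the
    observed-day manifest and all their rows are removed, mimicking
    collection outages.
    """
    if n_missing == 0:
        return panel
    candidates = [d for d in panel.observed_days if d != min(panel.observed_days)]
    if n_missing >= len(panel.observed_days):
        raise StorefluxError(
            f"cannot mask {n_missing} of {len(panel.observed_days)} observed days"
        )
    rng = np.random.default_rng(seed)
    masked = set(rng.choice(candidates, size=n_missing, replace=False).tolist())
    keep_days = [d for d in panel.observed_days if d not in masked]
    frame = panel.frame[panel.frame["date"].isin(keep_days)].reset_index(drop=True)
    return make_panel(
        frame, panel.platform, panel.keyword, panel.span_days, keep_days, validate=False
    )
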