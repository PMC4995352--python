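"""End-to-end pipeline: simulate -> estimate -> screen -> subgroups -> report.

Produces plain CSV/JSON analogs of the study's result tables:

* ``table1.csv`` — unique apps in the day-1 search and over the whole span;
* ``table2.csv`` — search-result half-life and % remaining at study end;
* ``table3.csv`` — availability ("app") half-life and % remaining;
* ``table4.csv`` — both modes stratified by consensus clinical relevance;
* ``claims.csv`` — claim-keyword filter counts among relevant apps;
* ``report.json`` — everything above plus removal intervals, the full
  averaged curves with support counts, and the config/seed for provenance.

Any stage failure aborts with a stage-named error and removes partial
outputs, so an output directory is either complete or empty.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .errors import StorefluxError
from .panel import SnapshotPanel, read_panel, read_registry, write_panel, write_registry
from .screening import claim_keyword_filter, relevance_proportion
from .simulate import SimulationConfig, simulate_marketplace
from .subgroups import SubgroupSpec, subgroup_estimate
from .survival import (
    HalfLifeResult,
    all_cohort_series,
    average_series,
    estimate_half_life,
    half_life,
    removal_interval,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    panel_path: Optional[str] = None  # load instead of simulating
    registry_path: Optional[str] = None
    modes: tuple = ("search", "availability")
    min_series: int = 20
    absorbing: bool = False
    subgroup_specs: tuple = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "simulation" in data:
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        if "subgroup_specs" in data:
            data["subgroup_specs"] = tuple(SubgroupSpec(**s) for s in data["subgroup_specs"])
        if "modes" in data:
            data["modes"] = tuple(data["modes"])
        return cls(**data)


def count_unique_apps(panel: SnapshotPanel) -> tuple[int, int]:
    """(apps in the day-1 search results, distinct apps ever in the results).

    The total accumulates monotonically over the study, so it is always at
    least the day-1 count.
    """
    f = panel.frame
    searched = f[f["in_search"]]
    day1 = int((searched["date"] == 1).sum())
    total = int(searched["app_id"].nunique())
    return day1, total


def _fmt_halflife(res: HalfLifeResult, span: int) -> str:
    return f">{span}" if res.censored else str(res.half_life_days)


def _curve_payload(curve) -> dict:
    return {
        "mode": curve.mode,
        "min_series": curve.min_series,
        "offsets": sorted(curve.points),
        "proportion": [curve.points[t] for t in sorted(curve.points)],
        "support": {str(t): c for t, c in sorted(curve.support.items())},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``). The run
    is a pure function of the config: identical config and seed give a
    byte-identical bundle.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []

    def _path(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        written.append(p)
        return p

    stage = "setup"
    try:
        t0 = time.perf_counter()
        stage = "simulate"
        if config.panel_path:
            panel = read_panel(config.panel_path)
            registry = read_registry(config.registry_path) if config.registry_path else None
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            panel, registry, truth = simulate_marketplace(sim)
            panel_path = _path("panel.csv")
            write_panel(panel, panel_path)
            written.append(panel_path + ".meta.json")
            write_registry(registry, _path("registry.jsonl"))
            truth.table.to_csv(_path("truth.csv"), index=False)
        logger.info("stage simulate done in %.2fs", time.perf_counter() - t0)

        stage = "counts"
        day1, total = count_unique_apps(panel)
        pd.DataFrame(
            {
                "keyword": [panel.keyword],
                "platform": [panel.platform],
                "apps_on_first_day": [day1],
                "total_apps": [total],
            }
        ).to_csv(_path("table1.csv"), index=False)

        stage = "estimate"
        t0 = time.perf_counter()
        curves, results = {}, {}
        for mode in config.modes:
            curves[mode], results[mode] = estimate_half_life(
                panel, mode, min_series=config.min_series, absorbing=config.absorbing
            )
        for mode, table_name in (("search", "table2.csv"), ("availability", "table3.csv")):
            if mode not in results:
                continue
            res = results[mode]
            pd.DataFrame(
                {
                    "keyword": [panel.keyword],
                    "platform": [panel.platform],
                    "half_life_days": [_fmt_halflife(res, panel.span_days)],
                    "remaining_at_end_pct": [round(100 * res.remaining_at_end, 1)],
                }
            ).to_csv(_path(table_name), index=False)
        logger.info("stage estimate done in %.2fs", time.perf_counter() - t0)

        stage = "screen"
        claims_rows, relevant_ids = [], frozenset()
        if registry is not None:
            relevant_ids = frozenset(
                rec.app_id for rec in registry if rec.consensus_relevant
            )
            n_rel_total = len(relevant_ids)
            n_matched = 0
            for rec in registry:
                matched, kws = claim_keyword_filter(rec.description)
                rec.claim_match = matched
                rec.claim_keywords = kws
                if rec.consensus_relevant and matched:
                    n_matched += 1
            write_registry(registry, _path("registry_screened.jsonl"))
            searched_ids = set(panel.frame.loc[panel.frame["in_search"], "app_id"])
            n_rel_searched = len(relevant_ids & searched_ids)
            claims_rows.append(
                {
                    "platform": panel.platform,
                    "n_relevant": n_rel_total,
                    "n_relevant_in_search": n_rel_searched,
                    "relevance_pct_of_searched": relevance_proportion(
                        [(n_rel_searched, len(searched_ids))]
                    ),
                    "n_claim_keyword_matched": n_matched,
                }
            )
            pd.DataFrame(claims_rows).to_csv(_path("claims.csv"), index=False)

        stage = "stratify"
        table4_rows, strata_curves = [], {}
        removal = {}
        if registry is not None:
            app_ids = set(panel.frame["app_id"])
            strata = {
                "all": frozenset(app_ids),
                "relevant": relevant_ids,
                "not_relevant": frozenset(app_ids - relevant_ids),
            }
            for label, members in strata.items():
                row = {"platform": panel.platform, "subgroup": label}
                for mode in config.modes:
                    series = all_cohort_series(
                        panel,
                        mode,
                        absorbing=config.absorbing,
                        baseline_per_day=lambda d, m=members: m,
                    )
                    if not series:
                        continue
                    curve = average_series(series, min_series=config.min_series)
                    res = half_life(curve)
                    strata_curves[f"{label}:{mode}"] = curve
                    row[f"{mode}_half_life_days"] = _fmt_halflife(res, panel.span_days)
                    row[f"{mode}_remaining_pct"] = round(100 * res.remaining_at_end, 1)
                    if label == "relevant" and mode == "availability":
                        searched_ids = set(
                            panel.frame.loc[panel.frame["in_search"], "app_id"]
                        )
                        n_rel = len(members & searched_ids)
                        try:
                            removal["days_per_relevant_app_removal"] = removal_interval(
                                [(n_rel, res.remaining_at_end)], panel.span_days
                            )
                        except StorefluxError:
                            removal["days_per_relevant_app_removal"] = None
                table4_rows.append(row)
            pd.DataFrame(table4_rows).to_csv(_path("table4.csv"), index=False)

        stage = "subgroups"
        subgroup_rows = []
        for spec in config.subgroup_specs:
            for mode in config.modes:
                curve, res = subgroup_estimate(
                    panel, spec, mode, min_series=config.min_series, absorbing=config.absorbing
                )
                subgroup_rows.append(
                    {
                        "metric": spec.metric,
                        "which": spec.which,
                        "size": spec.size,
                        "mode": mode,
                        "half_life_days": _fmt_halflife(res, panel.span_days),
                        "remaining_pct": round(100 * res.remaining_at_end, 1),
                        "n_series": res.n_series,
                    }
                )
        if subgroup_rows:
            pd.DataFrame(subgroup_rows).to_csv(_path("subgroups.csv"), index=False)

        stage = "report"
        report = {
            "storeflux_version": __version__,
            "seed": config.seed,
            "config": {
                "modes": list(config.modes),
                "min_series": config.min_series,
                "absorbing": config.absorbing,
                "simulation": None
                if config.panel_path
                else dataclasses.asdict(dataclasses.replace(config.simulation, seed=config.seed)),
            },
            "table1": {"apps_on_first_day": day1, "total_apps": total},
            "half_life": {
                mode: {
                    "half_life_days": results[mode].half_life_days,
                    "censored": results[mode].censored,
                    "remaining_at_end_pct": round(100 * results[mode].remaining_at_end, 1),
                    "n_series": results[mode].n_series,
                }
                for mode in results
            },
            "curves": {mode: _curve_payload(curves[mode]) for mode in curves},
            "strata": table4_rows,
            "strata_curves": {k: _curve_payload(c) for k, c in strata_curves.items()},
            "claims": claims_rows,
            "removal_intervals": removal,
            "subgroups": subgroup_rows,
        }
        with open(_path("report.json"), "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise StorefluxError(f"pipeline stage {stage!r} failed: {exc}") from exc
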