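"""Synthetic marketplace: determinism, conservation, and analytic checks."""

import numpy as np
import pandas as pd
import pytest

from storeflux import (
    ConfigError,
    SimulationConfig,
    StorefluxError,
    claim_keyword_filter,
    generate_descriptions,
    mask_missing_days,
    simulate_marketplace,
)
from storeflux.simulate import NONRELEVANT_TEMPLATES, RELEVANT_TEMPLATES


def small_config(**kw):
    base = dict(
        n_initial_apps=30,
        arrival_rate=0.5,
        removal_hazard_relevant=0.01,
        removal_hazard_nonrelevant=0.01,
        search_window_k=20,
        span_days=40,
        n_missing_days=5,
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("relevance_fraction", 1.5),
            ("removal_hazard_relevant", -0.1),
            ("claim_fraction", 2.0),
            ("n_initial_apps", 0),
            ("search_window_k", 0),
            ("span_days", 0),
            ("arrival_rate", -1.0),
            ("platform", "windows"),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            simulate_marketplace(small_config(**{field: value}))

    def test_missing_days_must_fit_in_span(self):
        with pytest.raises(ConfigError, match="n_missing_days"):
            small_config(n_missing_days=40, span_days=40).validate()


class TestDeterminismAndConservation:
    def test_same_seed_same_panel(self):
        cfg = small_config(seed=12)
        p1, r1, t1 = simulate_marketplace(cfg)
        p2, r2, t2 = simulate_marketplace(cfg)
        assert p1.frame.equals(p2.frame)
        assert p1.observed_days == p2.observed_days
        assert t1.table.equals(t2.table)
        assert [a.description for a in r1] == [a.description for a in r2]

    def test_different_seed_different_panel(self):
        p1, _, _ = simulate_marketplace(small_config(seed=1))
        p2, _, _ = simulate_marketplace(small_config(seed=2))
        assert not p1.frame.equals(p2.frame)

    def test_every_observation_belongs_to_registry(self):
        panel, registry, _ = simulate_marketplace(small_config(seed=3))
        assert set(panel.frame["app_id"]) <= set(registry.app_ids)

    def test_no_observations_outside_app_lifetime(self):
        panel, _, truth = simulate_marketplace(small_config(seed=4))
        merged = panel.frame.merge(truth.table, on="app_id")
        assert (merged["date"] >= merged["arrival_day"]).all()
        removed = merged[merged["removal_day"].notna()]
        assert (removed["date"] < removed["removal_day"]).all()

    def test_search_window_truncation(self):
        panel, _, truth = simulate_marketplace(small_config(seed=5, search_window_k=12))
        per_day = panel.frame.groupby("date")["in_search"].sum()
        alive_per_day = panel.frame.groupby("date").size()
        assert (per_day == np.minimum(12, alive_per_day)).all()

    def test_ranks_are_a_permutation_each_day(self):
        panel, _, _ = simulate_marketplace(small_config(seed=6))
        for _, grp in panel.frame[panel.frame["in_search"]].groupby("date"):
            ranks = sorted(grp["rank"].astype(int))
            assert ranks == list(range(1, len(ranks) + 1))

    def test_panel_passes_its_own_validation(self):
        from storeflux import validate_panel

        panel, _, _ = simulate_marketplace(small_config(seed=7))
        validate_panel(panel)


class TestNoRemovalLimit:
    def test_everything_survives_forever(self):
        cfg = small_config(
            removal_hazard_relevant=0.0,
            removal_hazard_nonrelevant=0.0,
            arrival_rate=0.0,
            search_window_k=100,
            n_missing_days=0,
        )
        panel, _, _ = simulate_marketplace(cfg)
        per_day = panel.frame.groupby("date").agg(
            n=("app_id", "size"), searched=("in_search", "all"), avail=("available", "all")
        )
        assert (per_day["n"] == cfg.n_initial_apps).all()
        assert per_day["searched"].all() and per_day["avail"].all()


class TestAnalyticSurvival:
    def test_geometric_availability_fraction(self):
        """Availability on day d follows (1-h)^(d-1) under constant hazard."""
        h, n, span, n_seeds = 0.01, 1000, 200, 10
        fracs = []
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_initial_apps=n,
                arrival_rate=0.0,
                removal_hazard_relevant=h,
                removal_hazard_nonrelevant=h,
                search_window_k=2 * n,
                span_days=span,
                n_missing_days=0,
                seed=seed,
            )
            panel, _, _ = simulate_marketplace(cfg)
            fracs.append((panel.frame["date"] == span).sum() / n)
        expected = (1 - h) ** (span - 1)
        se = np.sqrt(expected * (1 - expected) / n) / np.sqrt(n_seeds)
        assert abs(np.mean(fracs) - expected) < 3 * se

    def test_empirical_hazard_recovers_configuration(self):
        """Removals per app-day at risk estimate the configured hazard."""
        h = 0.01
        cfg = SimulationConfig(
            n_initial_apps=1500,
            arrival_rate=0.0,
            removal_hazard_relevant=h,
            removal_hazard_nonrelevant=h,
            search_window_k=3000,
            span_days=150,
            n_missing_days=0,
            seed=42,
        )
        _, _, truth = simulate_marketplace(cfg)
        t = truth.table
        last = np.where(
            t["removal_day"].notna(),
            np.minimum(t["removal_day"], cfg.span_days + 1) - 1,
            cfg.span_days,
        )
        exposure = (last - t["arrival_day"]).sum()  # app-days at risk of removal
        events = ((t["removal_day"].notna()) & (t["removal_day"] <= cfg.span_days)).sum()
        rate = events / exposure
        se = np.sqrt(h * (1 - h) / exposure)
        assert abs(rate - h) < 3 * se


class TestDescriptions:
    def test_claim_fraction_one_marks_every_relevant_app(self):
        cfg = small_config(seed=8, claim_fraction=1.0, relevance_fraction=0.5)
        _, registry, truth = simulate_marketplace(cfg)
        rel = dict(zip(truth.table["app_id"], truth.table["relevant"]))
        for rec in registry:
            matched, _ = claim_keyword_filter(rec.description)
            assert matched == bool(rel[rec.app_id])

    def test_claim_fraction_zero_and_clean_templates_never_match(self):
        cfg = small_config(seed=9, claim_fraction=0.0)
        _, registry, _ = simulate_marketplace(cfg)
        assert not any(claim_keyword_filter(rec.description)[0] for rec in registry)
        # the template pools themselves are keyword-free by construction
        for text in RELEVANT_TEMPLATES + NONRELEVANT_TEMPLATES:
            assert claim_keyword_filter(text) == (False, [])

    def test_claim_fraction_recovered_binomially(self):
        p, matched, n = 0.3, 0, 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_initial_apps=1000,
                arrival_rate=0.0,
                relevance_fraction=1.0,
                claim_fraction=p,
                search_window_k=1000,
                span_days=2,
                n_missing_days=0,
                seed=seed,
            )
            _, registry, truth = simulate_marketplace(cfg)
            matched += sum(claim_keyword_filter(rec.description)[0] for rec in registry)
            n += len(registry)
            # ground-truth flags agree exactly with the filter on synthetic text
            flags = dict(zip(truth.table["app_id"], truth.table["claim"]))
            assert all(
                claim_keyword_filter(rec.description)[0] == bool(flags[rec.app_id])
                for rec in registry
            )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(matched / n - p) < 3 * se


class TestMaskMissingDays:
    def test_zero_masking_is_identity(self):
        panel, _, _ = simulate_marketplace(small_config(seed=11, n_missing_days=0))
        masked = mask_missing_days(panel, 0, seed=1)
        assert masked.frame.equals(panel.frame)

    def test_study_accounting(self):
        cfg = small_config(
            seed=12, span_days=246, n_missing_days=35, n_initial_apps=10, arrival_rate=0.0
        )
        panel, _, _ = simulate_marketplace(cfg)
        assert len(panel.observed_days) == 211
        assert panel.span_days == 246
        assert 1 in panel.observed_days  # the baseline search is never masked

    def test_boundary_leaves_only_day_one(self):
        panel, _, _ = simulate_marketplace(small_config(seed=13, n_missing_days=0))
        n_obs = len(panel.observed_days)
        masked = mask_missing_days(panel, n_obs - 1, seed=2)
        assert masked.observed_days == [1]

    def test_over_masking_rejected(self):
        panel, _, _ = simulate_marketplace(small_config(seed=14, n_missing_days=0))
        with pytest.raises(StorefluxError):
            mask_missing_days(panel, len(panel.observed_days), seed=3)
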