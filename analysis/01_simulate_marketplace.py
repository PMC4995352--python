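#!/usr/bin/env python
"""Simulate the study-condition marketplace and write it under results/.

Generates a 246-day Android "depression" panel with a 190-result search
window, 35 masked collection days and removal hazards differing by clinical
relevance, plus the app registry (with synthetic descriptions and reviewer
labels) and the latent ground truth.
"""

import argparse
import pathlib

from storeflux import SimulationConfig, simulate_marketplace, write_panel, write_registry

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "marketplace"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    panel, registry, truth = simulate_marketplace(cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    write_panel(panel, str(OUT / "panel.csv"))
    write_registry(registry, str(OUT / "registry.jsonl"))
    truth.table.to_csv(OUT / "truth.csv", index=False)

    n_relevant = int(truth.table["relevant"].sum())
    print(f"simulated {len(registry)} apps over {cfg.span_days} days (seed {args.seed})")
    print(f"  observed days: {len(panel.observed_days)} (of {cfg.span_days})")
    print(f"  clinically relevant (ground truth): {n_relevant}")
    day1 = panel.frame[(panel.frame["date"] == 1) & panel.frame["in_search"]]
    print(f"  day-1 search results: {len(day1)} (window K={cfg.search_window_k})")
    print(f"  outputs in {OUT}")


if __name__ == "__main__":
    main()
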