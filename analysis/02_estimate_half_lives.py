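#!/usr/bin/env python
"""Estimate search-result and app half-lives from the simulated panel.

Reads results/marketplace/panel.csv (run 01_simulate_marketplace.py first),
computes one shifted-cohort averaged curve per mode with the >= 20-cohort
support rule, and writes the curves and a half-life summary table.
"""

import pathlib
import sys

import pandas as pd

from storeflux import estimate_half_life, read_panel

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel_path = BASE / "marketplace" / "panel.csv"
    if not panel_path.exists():
        sys.exit("run analysis/01_simulate_marketplace.py first")
    panel = read_panel(str(panel_path))

    rows, curve_frames = [], []
    for mode in ("search", "availability"):
        curve, res = estimate_half_life(panel, mode, min_series=20)
        reported = f">{panel.span_days}" if res.censored else str(res.half_life_days)
        rows.append(
            {
                "mode": mode,
                "half_life_days": reported,
                "remaining_at_end_pct": round(100 * res.remaining_at_end, 1),
                "last_offset": res.last_offset,
                "n_cohorts": res.n_series,
            }
        )
        offsets = sorted(curve.points)
        curve_frames.append(
            pd.DataFrame(
                {
                    "mode": mode,
                    "offset_days": offsets,
                    "proportion_remaining": [curve.points[t] for t in offsets],
                    "n_cohorts": [curve.support[t] for t in offsets],
                }
            )
        )
        print(
            f"{mode} half-life: {reported} days; "
            f"{rows[-1]['remaining_at_end_pct']}% remaining at the last reported offset "
            f"({res.last_offset} days, {res.n_series} cohorts)"
        )

    summary = pd.DataFrame(rows)
    summary.to_csv(BASE / "half_lives.csv", index=False)
    pd.concat(curve_frames).to_csv(BASE / "averaged_curves.csv", index=False)
    print(f"wrote {BASE / 'half_lives.csv'} and {BASE / 'averaged_curves.csv'}")


if __name__ == "__main__":
    main()
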