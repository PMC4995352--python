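#!/usr/bin/env python
"""Half-lives for top/bottom-25 subgroups by store-visible metrics.

For each metric (search rank, review count, star rating, download band) the
subgroup membership is re-selected at every cohort's start day; both modes
are estimated. Small subgroup sizes make these noisy by construction — the
cohort counts are written alongside every estimate.
"""

import pathlib
import sys

import pandas as pd

from storeflux import EmptySubgroupError, SubgroupSpec, read_panel, subgroup_estimate

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"
METRICS = ("rank", "n_reviews", "star_rating", "download_bucket")


def main() -> None:
    panel_path = BASE / "marketplace" / "panel.csv"
    if not panel_path.exists():
        sys.exit("run analysis/01_simulate_marketplace.py first")
    panel = read_panel(str(panel_path))

    rows = []
    for metric in METRICS:
        for which in ("top", "bottom"):
            spec = SubgroupSpec(metric, which, 25)
            for mode in ("search", "availability"):
                try:
                    curve, res = subgroup_estimate(panel, spec, mode, min_series=20)
                except EmptySubgroupError:
                    print(f"{metric}/{which} {mode}: no eligible subgroup")
                    continue
                reported = f">{panel.span_days}" if res.censored else str(res.half_life_days)
                rows.append(
                    {
                        "metric": metric,
                        "which": which,
                        "mode": mode,
                        "half_life_days": reported,
                        "remaining_pct": round(100 * res.remaining_at_end, 1),
                        "n_cohorts": res.n_series,
                    }
                )
                print(
                    f"{metric}/{which} {mode}: t1/2 {reported} days, "
                    f"{rows[-1]['remaining_pct']}% remaining ({res.n_series} cohorts)"
                )

    pd.DataFrame(rows).to_csv(BASE / "subgroup_half_lives.csv", index=False)
    print(f"wrote {BASE / 'subgroup_half_lives.csv'}")


if __name__ == "__main__":
    main()
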