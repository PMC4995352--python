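#!/usr/bin/env python
"""Screen the simulated registry: relevance proportions and claim keywords.

Applies the effectiveness-claim keyword filter to every store description,
compares it against the simulation's ground-truth claim flags, and reports
the relevance proportion among apps that ever appeared in the search
results. Also recomputes the pooled relevance percentage from the published
per-platform screening counts (197/623 Android, 150/359 iOS).
"""

import pathlib
import sys

import pandas as pd

from storeflux import claim_keyword_filter, read_panel, read_registry, relevance_proportion

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    reg_path = BASE / "marketplace" / "registry.jsonl"
    if not reg_path.exists():
        sys.exit("run analysis/01_simulate_marketplace.py first")
    registry = read_registry(str(reg_path))
    panel = read_panel(str(BASE / "marketplace" / "panel.csv"))
    truth = pd.read_csv(BASE / "marketplace" / "truth.csv")

    searched = set(panel.frame.loc[panel.frame["in_search"], "app_id"])
    relevant = {r.app_id for r in registry if r.consensus_relevant}
    prop = relevance_proportion([(len(relevant & searched), len(searched))])
    print(f"relevance among searched apps: {len(relevant & searched)}/{len(searched)} = {prop}%")

    flags = dict(zip(truth["app_id"], truth["claim"]))
    n_match = n_agree = 0
    for rec in registry:
        matched, _ = claim_keyword_filter(rec.description)
        n_match += matched
        n_agree += matched == bool(flags[rec.app_id])
    print(f"claim filter matched {n_match}/{len(registry)} descriptions; "
          f"agreement with ground truth {n_agree}/{len(registry)}")

    pooled = relevance_proportion([(197, 623), (150, 359)])
    print(f"published-count pooled relevance: {pooled}%")

    pd.DataFrame(
        [
            {
                "n_searched": len(searched),
                "n_relevant_searched": len(relevant & searched),
                "relevance_pct": prop,
                "n_claim_matched": n_match,
                "filter_truth_agreement": n_agree / len(registry),
                "published_pooled_relevance_pct": pooled,
            }
        ]
    ).to_csv(BASE / "screening.csv", index=False)
    print(f"wrote {BASE / 'screening.csv'}")


if __name__ == "__main__":
    main()
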