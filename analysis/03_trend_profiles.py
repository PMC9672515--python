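"""Trend-profile enrichment of the differential features over the 3 stages.

Assigns each DE miRNA's and circRNA's stage-mean series to one of 25
step profiles (c = 2) by Pearson correlation and tests profile
occupancy against a stage-label permutation null.  The headline check
is the down-vs-up contrast: differential miRNAs concentrate in falling
profiles, differential circRNAs in rising ones.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RUN_DIR, make_config

from cernapipe.pipeline import stage_trends


def main() -> None:
    cfg = make_config()
    stage_trends(cfg)
    print(f"wrote trend tables to {RUN_DIR / 'trends'}")
    for layer in ("miRNA", "circRNA"):
        enr = pd.read_csv(RUN_DIR / "trends" / f"trend_enrichment_{layer}.tsv", sep="\t")
        occupied = enr[enr["observed_count"] > 0]
        top = occupied.sort_values(["p_value", "profile_id"]).iloc[0]
        direction = "falling" if top["net_change"] < 0 else "rising"
        n_sig = int(enr["significant"].sum())
        print(
            f"  {layer:8s} {int(enr['observed_count'].sum())} DE features over "
            f"{len(occupied)} occupied profiles; {n_sig} profiles significant; "
            f"top profile steps ({top['steps']}) is {direction} "
            f"(observed {int(top['observed_count'])}, expected {top['expected_count']:.1f}, "
            f"p = {top['p_value']:.3g})"
        )


if __name__ == "__main__":
    main()
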