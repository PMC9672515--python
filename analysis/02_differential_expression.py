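"""Call differential expression for every pairwise stage comparison.

miRNA counts are CPM-normalized against small-RNA library sizes and
tested with a Welch t-test on the log scale (significant at P < 0.05);
mRNAs use the same test plus a |log2FC| > 1 gate; circRNA back-splice
junction counts are SRPBM-normalized and use the same dual rule.
Writes per-layer, per-comparison tables plus the cross-comparison
overlap and the highly expressed miRNA list under results/run/de/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RUN_DIR, make_config

from cernapipe.pipeline import stage_de


def main() -> None:
    cfg = make_config()
    stage_de(cfg)
    print(f"wrote DE tables to {RUN_DIR / 'de'}")
    for layer in ("miRNA", "mRNA", "circRNA"):
        parts = []
        for label in ("30M_vs_6M", "30M_vs_18M", "18M_vs_6M"):
            de = pd.read_csv(RUN_DIR / "de" / f"de_{layer}_{label}.tsv", sep="\t", index_col=0)
            sig = de[de["significant"]]
            parts.append(
                f"{label}: {len(sig)} ({(sig['direction'] == 'up').sum()} up, "
                f"{(sig['direction'] == 'down').sum()} down)"
            )
        print(f"  {layer:8s} " + "; ".join(parts))
    overlap = json.loads((RUN_DIR / "de" / "overlap.json").read_text())
    triple = overlap["miRNA"].get("18M_vs_6M+30M_vs_18M+30M_vs_6M", 0)
    print(f"  miRNAs significant in all three comparisons: {triple}")
    high = pd.read_csv(RUN_DIR / "de" / "highly_expressed_mirna.tsv", sep="\t")
    print(f"  highly expressed miRNAs (mean CPM > 1000): {len(high)}")


if __name__ == "__main__":
    main()
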