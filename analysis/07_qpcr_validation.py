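"""qRT-PCR-style validation of selected differential features by 2^-ddCt.

Emulates the wet-lab confirmation step: for the six most significant
differential miRNAs and circRNAs (30M vs 6M), synthetic Ct values are
derived from the normalized stage means (one PCR cycle per doubling,
stable reference gene), and the 2^-ddCt relative expression is compared
with the RNA-seq fold change — directions should agree.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import ROOT, RUN_DIR, make_config

from cernapipe import io_formats as io
from cernapipe.expression import compute_srpbm, normalize_cpm
from cernapipe.qpcr import ddct_table


def synthetic_ct(norm_value: float, offset: float = 30.0) -> float:
    """Ct falls by one cycle per doubling of template."""
    return offset - np.log2(norm_value + 0.5)


def main() -> None:
    cfg = make_config()
    indir = RUN_DIR / "inputs"
    design = io.read_design(indir / "design.tsv")
    totals = pd.read_csv(indir / "mapped_totals.tsv", sep="\t", index_col=0)
    rows = []
    for layer, fname in (("miRNA", "counts_mirna.tsv"), ("circRNA", "counts_circ.tsv")):
        counts = io.read_counts(indir / fname, design, layer=layer)
        norm = (
            normalize_cpm(counts, totals["miRNA"])
            if layer == "miRNA"
            else compute_srpbm(counts, totals["circRNA"])
        )
        de = pd.read_csv(
            RUN_DIR / "de" / f"de_{layer}_30M_vs_6M.tsv", sep="\t", index_col=0
        )
        picks = de[de["significant"]].sort_values("p_value").head(6)
        test = design.loc[design["stage"] == "30M", "sample_id"]
        cal = design.loc[design["stage"] == "6M", "sample_id"]
        for fid in picks.index:
            rows.append(
                {
                    "assay": fid,
                    "layer": layer,
                    "ct_target_test": synthetic_ct(norm.data.loc[fid, test].mean()),
                    "ct_ref_test": 20.0,
                    "ct_target_cal": synthetic_ct(norm.data.loc[fid, cal].mean()),
                    "ct_ref_cal": 20.0,
                    "rnaseq_log2fc": de.loc[fid, "log2fc"],
                }
            )
    ct = ddct_table(pd.DataFrame(rows))
    out = ROOT / "results" / "qpcr_validation.tsv"
    ct.to_csv(out, sep="\t", index=False, lineterminator="\n")
    agree = (np.sign(np.log2(ct["relative_expression"])) == np.sign(ct["rnaseq_log2fc"]))
    print(f"wrote {out}")
    print(ct[["assay", "layer", "ddct", "relative_expression", "rnaseq_log2fc"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"direction agreement with RNA-seq: {int(agree.sum())}/{len(ct)}")


if __name__ == "__main__":
    main()
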