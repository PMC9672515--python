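"""Direction-constrained mRNA-miRNA-circRNA triad assembly.

A competing-endogenous-RNA triad (g, m, c) is emitted for one stage
comparison when all three members are significantly differentially
expressed, the miRNA targets both the mRNA and the circRNA (passing
target pairs), and the miRNA's direction opposes both partners' —
which forces mRNA/circRNA concordance and yields exactly the two
modes down-up-down and up-down-up (ordered mRNA-miRNA-circRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CeRNATriad", "assemble_triads", "hub_stats", "triads_to_frame"]

MODES = ("down-up-down", "up-down-up")


@dataclass(frozen=True, order=True)
class CeRNATriad:
    mrna_id: str
    mirna_id: str
    circ_id: str
    comparison: str
    mode: str


def _sig_directions(de: pd.DataFrame) -> dict[str, str]:
    sig = de[de["significant"]]
    return dict(zip(sig.index, sig["direction"]))


def assemble_triads(
    de_mrna: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_circ: pd.DataFrame,
    target_pairs: pd.DataFrame,
) -> list[CeRNATriad]:
    """Exhaustive, duplicate-free triad list in lexicographic order.

    DE inputs are ``call_de`` outputs for one shared comparison; only
    target pairs with ``passes`` are used.
    """
    comparisons = {
        c
        for de in (de_mrna, de_mirna, de_circ)
        for c in de["comparison"].unique()
    }
    if len(comparisons) > 1:
        raise ValueError(f"mixed comparisons in DE inputs: {sorted(comparisons)}")
    comparison = next(iter(comparisons)) if comparisons else ""

    dir_g = _sig_directions(de_mrna)
    dir_m = _sig_directions(de_mirna)
    dir_c = _sig_directions(de_circ)

    passing = target_pairs[target_pairs["passes"]]
    edges_mrna: dict[str, list[str]] = {}
    edges_circ: dict[str, list[str]] = {}
    for row in passing.itertuples():
        if row.layer == "mRNA":
            edges_mrna.setdefault(row.mirna_id, []).append(row.target_id)
        elif row.layer == "circRNA":
            edges_circ.setdefault(row.mirna_id, []).append(row.target_id)

    triads = []
    for m, dm in dir_m.items():
        want = "down" if dm == "up" else "up"
        for g in edges_mrna.get(m, ()):
            if dir_g.get(g) != want:
                continue
            for c in edges_circ.get(m, ()):
                if dir_c.get(c) != want:
                    continue
                mode = f"{want}-{dm}-{want}"
                triads.append(CeRNATriad(g, m, c, comparison, mode))
    return sorted(set(triads))


def triads_to_frame(triads: list[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.mrna_id, t.mirna_id, t.circ_id, t.comparison, t.mode) for t in triads],
        columns=["mrna_id", "mirna_id", "circ_id", "comparison", "mode"],
    )


def hub_stats(
    target_pairs: pd.DataFrame | None = None,
    triads: list[CeRNATriad] | None = None,
) -> pd.DataFrame:
    """Per-miRNA degree table: #mRNA targets, #circRNA targets, #triads.

    Sorted by total target degree descending, ties by miRNA id.
    """
    counts: dict[str, list[int]] = {}
    if target_pairs is not None and len(target_pairs):
        passing = target_pairs[target_pairs["passes"]]
        for row in passing.itertuples():
            entry = counts.setdefault(row.mirna_id, [0, 0, 0])
            if row.layer == "mRNA":
                entry[0] += 1
            elif row.layer == "circRNA":
                entry[1] += 1
    for t in triads or ():
        counts.setdefault(t.mirna_id, [0, 0, 0])[2] += 1
    df = pd.DataFrame(
        [(m, a, b, c) for m, (a, b, c) in counts.items()],
        columns=["mirna_id", "n_mrna_targets", "n_circ_targets", "n_triads"],
    )
    if len(df):
        df["_total"] = df["n_mrna_targets"] + df["n_circ_targets"]
        df = (
            df.sort_values(["_total", "mirna_id"], ascending=[False, True], kind="stable")
            .drop(columns="_total")
            .reset_index(drop=True)
        )
    return df
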