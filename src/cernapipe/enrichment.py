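"""Over-representation analysis of gene lists against GMT gene sets.

The statistic is the upper hypergeometric tail: with a universe of N
genes, K of which belong to a set, the probability of observing at least
k set members in a list of n.  Significance at raw P < 0.05 (strict, no
correction by default; Benjamini-Hochberg available as a switch).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

__all__ = ["hypergeometric_tail", "enrich"]


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: hits in the list; K: set size in the universe; n: list size;
    N: universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_list,
    gene_sets: dict[str, set],
    universe,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One hypergeometric result per gene set intersecting the universe.

    Rows are ordered by (p_value, set_id).  Raises if the list contains
    genes outside the universe.
    """
    universe = set(universe)
    genes = set(gene_list)
    offenders = sorted(genes - universe)
    if offenders:
        raise ValueError(f"gene list items outside the universe: {offenders}")
    N, n = len(universe), len(genes)
    rows = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(genes & members)
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeometric_tail(k, K, n, N),
            }
        )
    df = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p_value"])
    if len(df) and bh_correct:
        from .expression import _bh_adjust

        df["p_value"] = _bh_adjust(df["p_value"].to_numpy())
    df["significant"] = df["p_value"] < 0.05
    if len(df):
        df = df.sort_values(["p_value", "set_id"], kind="stable").reset_index(drop=True)
    return df
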