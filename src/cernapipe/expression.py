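"""Normalization and staged differential expression.

Counts are normalized to CPM (miRNA, mRNA) or SRPBM (circRNA back-splice
junction counts: spliced reads per billion mapped reads).  Differential
expression between two stages is a per-feature two-sided Welch t-test on
normalized values with a pseudocount-stabilized log2 fold change, and a
per-layer significance rule: miRNA requires P < 0.05; mRNA and circRNA
require P < 0.05 and |log2FC| > 1 (all strict, no multiple-testing
correction by default, mirroring the source analysis; Benjamini-Hochberg
is available as an opt-in switch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DEThresholds",
    "default_thresholds",
    "normalize_cpm",
    "compute_srpbm",
    "log2_fold_change",
    "welch_t_test",
    "call_de",
    "overlap_de",
    "filter_highly_expressed",
    "comparison_label",
]

LAYERS = ("miRNA", "mRNA", "circRNA")
UNITS = ("raw", "CPM", "SRPBM")


@dataclass
class ExpressionMatrix:
    """Features x samples matrix with a units tag and layer label."""

    data: pd.DataFrame  # index: feature ids, columns: sample ids
    units: str = "raw"
    layer: str = "mRNA"

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        vals = self.data.to_numpy()
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def normalize_cpm(
    counts: ExpressionMatrix, library_sizes: pd.Series | None = None
) -> ExpressionMatrix:
    """Counts per million: count / sample total * 1e6.

    By default the sample total is the matrix column sum, so each column
    sums to 1e6.  When the count matrix covers only a subset of the
    library (e.g. simulated features drawn from a larger transcriptome),
    pass ``library_sizes`` — per-sample total mapped reads — as the
    denominator instead; this avoids the closure artifact where a few
    strongly changing features distort every other feature's CPM.
    """
    if counts.units != "raw":
        raise ValueError(f"normalize_cpm expects raw counts, got {counts.units}")
    if library_sizes is None:
        totals = counts.data.sum(axis=0)
    else:
        missing = [s for s in counts.sample_ids if s not in library_sizes.index]
        if missing:
            raise ValueError(f"library sizes missing for sample(s) {missing}")
        totals = library_sizes.loc[counts.sample_ids].astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has non-positive total count")
    return ExpressionMatrix(counts.data / totals * 1e6, units="CPM", layer=counts.layer)


def compute_srpbm(
    junction_counts: ExpressionMatrix, total_mapped_reads: pd.Series
) -> ExpressionMatrix:
    """Spliced reads per billion mapped: junction reads / total mapped * 1e9.

    ``total_mapped_reads`` is indexed by sample id (total mapped reads of
    the RNA-seq library, not total junction reads).
    """
    if junction_counts.units != "raw":
        raise ValueError(f"compute_srpbm expects raw counts, got {junction_counts.units}")
    missing = [s for s in junction_counts.sample_ids if s not in total_mapped_reads.index]
    if missing:
        raise ValueError(f"total mapped reads missing for sample(s) {missing}")
    totals = total_mapped_reads.loc[junction_counts.sample_ids].astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"non-positive total mapped reads for sample {bad!r}")
    return ExpressionMatrix(
        junction_counts.data / totals * 1e9, units="SRPBM", layer=junction_counts.layer
    )


def log2_fold_change(mean_b: float, mean_a: float, pseudocount: float = 0.5) -> float:
    """log2((mean_b + pc) / (mean_a + pc)); antisymmetric in its arguments."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if mean_b < 0 or mean_a < 0:
        raise ValueError("group means must be non-negative")
    return float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))


def welch_t_test(group_b: np.ndarray, group_a: np.ndarray) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Degenerate convention: both groups zero-variance -> p = 1 if the means
    are equal, else p = 0.
    """
    b = np.asarray(group_b, dtype=float)
    a = np.asarray(group_a, dtype=float)
    if len(b) < 2 or len(a) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(b) == 0 and np.ptp(a) == 0:
        return 1.0 if b[0] == a[0] else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(b, a, equal_var=False).pvalue
    if np.isnan(p):  # defensive: degenerate inputs not caught above
        return 1.0 if b.mean() == a.mean() else 0.0
    return float(p)


@dataclass(frozen=True)
class DEThresholds:
    """Significance rule for one layer (strict inequalities)."""

    p_max: float = 0.05
    lfc_min: float | None = 1.0  # None: no fold-change gate (miRNA rule)
    pseudocount: float = 0.5
    bh_correct: bool = False


def default_thresholds(layer: str) -> DEThresholds:
    if layer == "miRNA":
        return DEThresholds(lfc_min=None)
    return DEThresholds(lfc_min=1.0)


def comparison_label(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def call_de(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    comparison: tuple[str, str],
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Per-feature DE statistics for one (later, earlier) stage comparison.

    The Welch test runs on log2(normalized value + pseudocount) — the
    log transform stabilizes the strongly mean-dependent count variance,
    which both calibrates the test and restores power at 3 replicates;
    the log2 fold change is computed from the natural-scale group means
    with the same pseudocount.  Returns a DataFrame indexed by feature id
    with columns comparison, log2fc, p_value, direction and significant;
    every feature is reported.  Direction is up when the later stage is
    higher (log2fc > 0).
    """
    if matrix.units == "raw":
        raise ValueError("call_de expects a normalized matrix (CPM or SRPBM)")
    if thresholds is None:
        thresholds = default_thresholds(matrix.layer)
    later, earlier = comparison
    for stage in (later, earlier):
        if stage not in set(design["stage"]):
            raise ValueError(f"stage {stage!r} not present in design")
    samples_b = design.loc[design["stage"] == later, "sample_id"].tolist()
    samples_a = design.loc[design["stage"] == earlier, "sample_id"].tolist()
    if len(samples_b) < 2 or len(samples_a) < 2:
        raise ValueError(
            f"comparison {comparison_label(comparison)} needs >= 2 replicates per stage"
        )
    B = matrix.data[samples_b].to_numpy(dtype=float)
    A = matrix.data[samples_a].to_numpy(dtype=float)

    lfc = np.array(
        [
            log2_fold_change(mb, ma, thresholds.pseudocount)
            for mb, ma in zip(B.mean(axis=1), A.mean(axis=1))
        ]
    )
    logB = np.log2(B + thresholds.pseudocount)
    logA = np.log2(A + thresholds.pseudocount)
    pvals = np.array([welch_t_test(logB[i], logA[i]) for i in range(B.shape[0])])
    p_eff = _bh_adjust(pvals) if thresholds.bh_correct else pvals

    sig = p_eff < thresholds.p_max
    if thresholds.lfc_min is not None:
        sig &= np.abs(lfc) > thresholds.lfc_min
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    sig &= direction != "none"

    return pd.DataFrame(
        {
            "comparison": comparison_label(comparison),
            "log2fc": lfc,
            "p_value": pvals,
            "direction": direction,
            "significant": sig,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def overlap_de(de_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region cardinalities for 2-3 named sets.

    Keys are sorted tuples of the set names whose exclusive intersection
    region the value counts; region sizes sum to the union size.
    """
    from itertools import combinations

    if not 2 <= len(de_sets) <= 3:
        raise ValueError("overlap_de supports 2 or 3 sets")
    names = sorted(de_sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = 0
    for feat in set().union(*de_sets.values()):
        member = tuple(n for n in names if feat in de_sets[n])
        regions[member] += 1
    return dict(sorted(regions.items()))


def filter_highly_expressed(matrix: ExpressionMatrix, threshold: float = 1000.0) -> list[str]:
    """Feature ids whose across-sample mean normalized value exceeds the
    threshold (strict >; the source analysis used mean norm value > 1,000)."""
    if matrix.units == "raw":
        raise ValueError("filter_highly_expressed expects a normalized matrix")
    means = matrix.data.mean(axis=1)
    return [fid for fid in matrix.feature_ids if means[fid] > threshold]
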