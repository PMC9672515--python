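"""Synthetic miRNA/mRNA/circRNA datasets with planted ground truth.

Emulates the statistical structure of a 3-stage (x3 replicates) tail-fat
profiling design: stage-dependent negative-binomial counts with
feature-wise log-normal baselines, mostly-downregulated differential
miRNAs and mostly-upregulated differential circRNAs across age, and
planted miRNA->mRNA / miRNA->circRNA target sites (reverse-complement
seed plus 3'-supplementary complementarity) that imply anti-correlated
ceRNA triads.  The planted truth is emitted alongside the data so every
downstream stage can be scored for recovery.

The count model is the mean-dispersion negative binomial,
variance = mu + phi * mu^2 with one shared dispersion phi.  Planted
differential features change monotonically over stages: each stage step
multiplies the mean by 2^(+-lfc_magnitude).  Library sizes are drawn
log-uniformly and enter as per-sample scale factors, so normalization is
actually exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .cerna import CeRNATriad
from .expression import ExpressionMatrix, comparison_label

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "implied_truth_triads",
    "write_dataset",
]

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass
class SimulationConfig:
    n_stages: int = 3
    stage_labels: tuple[str, ...] | None = None  # default 6M/18M/30M at 3 stages
    n_reps: int = 3
    n_mirna: int = 60
    n_mrna: int = 240
    n_circ: int = 100
    utr_len_range: tuple[int, int] = (200, 400)
    circ_len_range: tuple[int, int] = (200, 500)
    mirna_len_range: tuple[int, int] = (18, 26)
    frac_de_mirna: float = 0.3
    frac_de_mrna: float = 0.25
    frac_de_circ: float = 0.3
    lfc_magnitude: float = 1.5
    nb_dispersion: float = 0.1
    mean_log_mu: float = 5.3  # log-scale baseline mean (~200 counts)
    sd_log_mu: float = 1.2
    frac_mirna_down: float = 0.65  # DE miRNAs mainly decrease with age
    frac_circ_up: float = 0.6  # DE circRNAs mainly increase with age
    frac_mrna_up: float = 0.5
    n_planted_sites_per_pair: int = 1
    site_class_mix: dict = field(default_factory=lambda: {"8mer": 1.0})
    mrna_targets_per_mirna: int = 2
    circ_targets_per_mirna: int = 2
    decoy_targets_per_mirna: int = 1
    library_sizes: dict | None = None  # layer -> array per sample
    library_size_range: tuple[float, float] = (2e7, 5e7)
    # small-RNA libraries are orders of magnitude shallower, and miRNAs are
    # a large share of them, so high-expression miRNAs reach CPM > 1000
    mirna_library_size_range: tuple[float, float] = (1e6, 3e6)
    n_gene_sets: int = 20
    gene_set_size_range: tuple[int, int] = (10, 40)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        for name in ("n_reps", "n_mirna", "n_mrna", "n_circ", "n_planted_sites_per_pair"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frac_de_mirna", "frac_de_mrna", "frac_de_circ",
            "frac_mirna_down", "frac_circ_up", "frac_mrna_up",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lfc_magnitude <= 0 or self.nb_dispersion <= 0:
            raise ValueError("lfc_magnitude and nb_dispersion must be positive")
        lo, hi = self.mirna_len_range
        if not (18 <= lo <= hi <= 26):
            raise ValueError("mirna_len_range must lie within [18, 26]")
        if abs(sum(self.site_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("site_class_mix proportions must sum to 1")
        unknown = set(self.site_class_mix) - set(SITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown site class(es) {sorted(unknown)}")
        if self.stage_labels is not None and len(self.stage_labels) != self.n_stages:
            raise ValueError("stage_labels length must equal n_stages")

    @property
    def stages(self) -> tuple[str, ...]:
        if self.stage_labels is not None:
            return tuple(self.stage_labels)
        if self.n_stages == 3:
            return ("6M", "18M", "30M")
        return tuple(f"T{i}" for i in range(self.n_stages))

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        """All (later, earlier) stage pairs: 30vs6, 30vs18, 18vs6 order."""
        stages = self.stages
        out = []
        for j in range(len(stages) - 1, 0, -1):
            for i in range(j):
                out.append((stages[j], stages[i]))
        return out


@dataclass
class SyntheticTruth:
    """Planted ground truth: DE directions, target sites, implied triads."""

    de_features: pd.DataFrame  # feature_id, layer, comparison, direction
    planted_pairs: pd.DataFrame  # mirna_id, target_id, target_layer, site_positions, site_class, target_is_de
    planted_triads: pd.DataFrame  # mrna_id, mirna_id, circ_id, comparison, mode


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    circ_seqs: dict[str, str]
    counts: dict[str, ExpressionMatrix]  # layer -> raw counts
    design: pd.DataFrame
    circ_annotations: pd.DataFrame
    gene_sets: dict[str, set]
    mapped_totals: dict[str, pd.Series]  # layer -> total mapped reads per sample
    truth: SyntheticTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _site_window(rng: np.random.Generator, mirna_seq: str, site_class: str) -> tuple[str, int, int]:
    """(window, site offset within window, site length) for one planted site.

    The window covers the reverse complement of miRNA positions 2-17 plus
    the position-1 slot, so the seed class reads out as requested and the
    duplex carries 3'-supplementary complementarity (seed-only duplexes
    rarely clear the -20 kcal/mol gate).
    """
    window = list(revcomp(mirna_seq[1:17]))  # comp(m17)..comp(m2)
    m8c = _COMP[mirna_seq[7]]
    if site_class in ("8mer", "7mer-m8"):
        last = "A" if site_class == "8mer" else rng.choice(list("CGU"))
        window.append(last)
        return "".join(window), 9, 8 if site_class == "8mer" else 7
    # break the m8 complement so the class stays 7mer-A1 / 6mer
    choices = [b for b in "ACGU" if b != m8c]
    window[9] = choices[rng.integers(len(choices))]
    window.append("A" if site_class == "7mer-A1" else rng.choice(list("CGU")))
    return "".join(window), 10, 7 if site_class == "7mer-A1" else 6


def _plant_site(
    rng: np.random.Generator,
    seqs: dict[str, str],
    occupied: dict[str, list[tuple[int, int]]],
    target_id: str,
    mirna_seq: str,
    site_class: str,
) -> tuple[int, str]:
    """Overwrite a non-overlapping window of the target with a site;
    extends the target deterministically when no room is left.
    Returns (site position, site class)."""
    window, offset, _length = _site_window(rng, mirna_seq, site_class)
    w = len(window)
    taken = occupied.setdefault(target_id, [])
    for _attempt in range(200):
        seq = seqs[target_id]
        if len(seq) >= w:
            start = int(rng.integers(0, len(seq) - w + 1))
            if all(start + w + 1 <= s or start >= e + 1 for s, e in taken):
                seqs[target_id] = seq[:start] + window + seq[start + w :]
                taken.append((start, start + w))
                return start + offset, site_class
        # no free slot: grow the sequence and retry
        seqs[target_id] = seq + _random_seq(rng, 25)
    raise RuntimeError(f"could not place a site on {target_id}")


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Deterministic synthetic dataset: same config (incl. seed) -> same data."""
    rng = np.random.default_rng(config.rng_seed)
    stages = config.stages

    mirna_ids = [f"mir{i:04d}" for i in range(config.n_mirna)]
    mrna_ids = [f"g{i:04d}" for i in range(config.n_mrna)]
    circ_ids = [f"circ{i:04d}" for i in range(config.n_circ)]

    lo, hi = config.mirna_len_range
    mirna_seqs = {
        mid: _random_seq(rng, int(rng.integers(lo, hi + 1))) for mid in mirna_ids
    }
    lo, hi = config.utr_len_range
    utr_seqs = {gid: _random_seq(rng, int(rng.integers(lo, hi + 1))) for gid in mrna_ids}
    lo, hi = config.circ_len_range
    circ_seqs = {cid: _random_seq(rng, int(rng.integers(lo, hi + 1))) for cid in circ_ids}

    # ---- planted DE directions (+1 up, -1 down, 0 null), monotone over stages
    def _plant_directions(ids: list[str], frac_de: float, frac_up: float) -> dict[str, int]:
        n_de = int(round(frac_de * len(ids)))
        de_idx = rng.choice(len(ids), size=n_de, replace=False)
        dirs = {fid: 0 for fid in ids}
        for i in de_idx:
            dirs[ids[i]] = 1 if rng.random() < frac_up else -1
        return dirs

    dir_mirna = _plant_directions(mirna_ids, config.frac_de_mirna, 1 - config.frac_mirna_down)
    dir_mrna = _plant_directions(mrna_ids, config.frac_de_mrna, config.frac_mrna_up)
    dir_circ = _plant_directions(circ_ids, config.frac_de_circ, config.frac_circ_up)

    # ---- planted target sites
    class_names = sorted(config.site_class_mix)
    class_probs = np.array([config.site_class_mix[c] for c in class_names])
    occupied_utr: dict[str, list[tuple[int, int]]] = {}
    occupied_circ: dict[str, list[tuple[int, int]]] = {}
    pair_rows = []

    def _plant_pairs(mid: str, pool: list[str], seqs, occupied, layer: str, k: int, is_de: bool):
        chosen = [pool[i] for i in rng.choice(len(pool), size=min(k, len(pool)), replace=False)] if pool else []
        for tid in chosen:
            positions = []
            for _ in range(config.n_planted_sites_per_pair):
                cls = class_names[rng.choice(len(class_names), p=class_probs)]
                pos, cls = _plant_site(rng, seqs, occupied, tid, mirna_seqs[mid], cls)
                positions.append((pos, cls))
            pair_rows.append(
                {
                    "mirna_id": mid,
                    "target_id": tid,
                    "target_layer": layer,
                    "site_positions": ";".join(f"{p}:{c}" for p, c in positions),
                    "site_class": positions[0][1],
                    "target_is_de": is_de,
                }
            )

    de_mirnas = [m for m in mirna_ids if dir_mirna[m] != 0]
    for mid in de_mirnas:
        anti = -dir_mirna[mid]
        pool_g = [g for g in mrna_ids if dir_mrna[g] == anti]
        pool_c = [c for c in circ_ids if dir_circ[c] == anti]
        _plant_pairs(mid, pool_g, utr_seqs, occupied_utr, "mRNA", config.mrna_targets_per_mirna, True)
        _plant_pairs(mid, pool_c, circ_seqs, occupied_circ, "circRNA", config.circ_targets_per_mirna, True)
        null_g = [g for g in mrna_ids if dir_mrna[g] == 0]
        _plant_pairs(mid, null_g, utr_seqs, occupied_utr, "mRNA", config.decoy_targets_per_mirna, False)

    planted_pairs = pd.DataFrame(
        pair_rows,
        columns=["mirna_id", "target_id", "target_layer", "site_positions", "site_class", "target_is_de"],
    )

    # ---- design and counts
    design = pd.DataFrame(
        [
            {"sample_id": f"{stage}_r{rep}", "stage": stage, "replicate": rep}
            for stage in stages
            for rep in range(1, config.n_reps + 1)
        ]
    )
    sample_stage_idx = np.array([stages.index(s) for s in design["stage"]])

    def _simulate_layer(ids: list[str], dirs: dict[str, int], layer: str):
        n = len(ids)
        base = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=n)
        if config.library_sizes is not None and layer in config.library_sizes:
            lib = np.asarray(config.library_sizes[layer], dtype=float)
            if len(lib) != len(design):
                raise ValueError(f"library_sizes[{layer!r}] must have one entry per sample")
        else:
            size_range = (
                config.mirna_library_size_range if layer == "miRNA" else config.library_size_range
            )
            llo, lhi = np.log(size_range)
            lib = np.exp(rng.uniform(llo, lhi, size=len(design)))
        lib = np.round(lib).astype(int)
        factors = lib / np.exp(np.mean(np.log(lib)))
        d = np.array([dirs[fid] for fid in ids])
        stage_log2 = d[:, None] * config.lfc_magnitude * sample_stage_idx[None, :]
        mu = base[:, None] * (2.0 ** stage_log2) * factors[None, :]
        counts = _nb_counts(rng, mu, config.nb_dispersion)
        matrix = ExpressionMatrix(
            pd.DataFrame(counts, index=ids, columns=design["sample_id"].tolist()),
            units="raw",
            layer=layer,
        )
        totals = pd.Series(lib, index=design["sample_id"].tolist(), name="total_mapped")
        return matrix, totals

    counts: dict[str, ExpressionMatrix] = {}
    mapped_totals: dict[str, pd.Series] = {}
    for ids, dirs, layer in (
        (mirna_ids, dir_mirna, "miRNA"),
        (mrna_ids, dir_mrna, "mRNA"),
        (circ_ids, dir_circ, "circRNA"),
    ):
        counts[layer], mapped_totals[layer] = _simulate_layer(ids, dirs, layer)

    # ---- circRNA annotations (host genes drawn among the mRNA genes)
    ann_rows = []
    for cid in circ_ids:
        start = int(rng.integers(1_000, 1_000_000))
        ann_rows.append(
            {
                "circ_id": cid,
                "chrom": f"chr{int(rng.integers(1, 27))}",
                "start": start,
                "end": start + len(circ_seqs[cid]),
                "strand": "+" if rng.random() < 0.5 else "-",
                "host_gene": mrna_ids[int(rng.integers(config.n_mrna))],
            }
        )
    circ_annotations = pd.DataFrame(ann_rows)

    # ---- gene sets over the mRNA universe; one set collects planted targets
    slo, shi = config.gene_set_size_range
    gene_sets: dict[str, set] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(slo, shi + 1))
        members = rng.choice(config.n_mrna, size=min(size, config.n_mrna), replace=False)
        gene_sets[f"GS{i:03d}"] = {mrna_ids[j] for j in members}
    planted_genes = set(planted_pairs.loc[planted_pairs["target_layer"] == "mRNA", "target_id"])
    if planted_genes:
        gene_sets["GS_planted_targets"] = planted_genes

    # ---- truth tables
    de_rows = []
    for ids, dirs, layer in (
        (mirna_ids, dir_mirna, "miRNA"),
        (mrna_ids, dir_mrna, "mRNA"),
        (circ_ids, dir_circ, "circRNA"),
    ):
        for fid in ids:
            if dirs[fid] == 0:
                continue
            for comp in config.comparisons:
                de_rows.append(
                    {
                        "feature_id": fid,
                        "layer": layer,
                        "comparison": comparison_label(comp),
                        "direction": "up" if dirs[fid] > 0 else "down",
                    }
                )
    de_features = pd.DataFrame(de_rows, columns=["feature_id", "layer", "comparison", "direction"])

    truth = SyntheticTruth(de_features, planted_pairs, pd.DataFrame())
    triad_frames = []
    for comp in config.comparisons:
        triads = implied_truth_triads(truth, comparison_label(comp))
        triad_frames.append(
            pd.DataFrame(
                [(t.mrna_id, t.mirna_id, t.circ_id, t.comparison, t.mode) for t in triads],
                columns=["mrna_id", "mirna_id", "circ_id", "comparison", "mode"],
            )
        )
    truth.planted_triads = (
        pd.concat(triad_frames, ignore_index=True)
        if triad_frames
        else pd.DataFrame(columns=["mrna_id", "mirna_id", "circ_id", "comparison", "mode"])
    )

    return SyntheticDataset(
        config=config,
        mirna_seqs=mirna_seqs,
        utr_seqs=utr_seqs,
        circ_seqs=circ_seqs,
        counts=counts,
        design=design,
        circ_annotations=circ_annotations,
        gene_sets=gene_sets,
        mapped_totals=mapped_totals,
        truth=truth,
    )


def implied_truth_triads(truth: SyntheticTruth, comparison: str) -> list[CeRNATriad]:
    """Exhaustive triads implied by planted edges and planted directions
    for one comparison, lexicographically ordered."""
    de = truth.de_features
    de_cmp = de[de["comparison"] == comparison]
    dirs = {
        layer: dict(zip(sub["feature_id"], sub["direction"]))
        for layer, sub in de_cmp.groupby("layer")
    }
    dir_m = dirs.get("miRNA", {})
    dir_g = dirs.get("mRNA", {})
    dir_c = dirs.get("circRNA", {})

    edges_g: dict[str, set] = {}
    edges_c: dict[str, set] = {}
    for row in truth.planted_pairs.itertuples():
        if row.target_layer == "mRNA":
            edges_g.setdefault(row.mirna_id, set()).add(row.target_id)
        else:
            edges_c.setdefault(row.mirna_id, set()).add(row.target_id)

    triads = []
    for m, dm in dir_m.items():
        want = "down" if dm == "up" else "up"
        for g in edges_g.get(m, ()):
            if dir_g.get(g) != want:
                continue
            for c in edges_c.get(m, ()):
                if dir_c.get(c) != want:
                    continue
                triads.append(CeRNATriad(g, m, c, comparison, f"{want}-{dm}-{want}"))
    return sorted(set(triads))


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write every artifact of a synthetic dataset as plain text files."""
    from pathlib import Path

    from . import io_formats as io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_fasta(ds.mirna_seqs, out / "mirna.fa")
    io.write_fasta(ds.utr_seqs, out / "utr.fa")
    io.write_fasta(ds.circ_seqs, out / "circ.fa")
    io.write_design(ds.design, out / "design.tsv")
    for layer, fname in (("miRNA", "counts_mirna.tsv"), ("mRNA", "counts_mrna.tsv"), ("circRNA", "counts_circ.tsv")):
        io.write_counts(ds.counts[layer], out / fname)
    totals = pd.DataFrame(
        {layer: ser for layer, ser in ds.mapped_totals.items()}
    )
    totals.to_csv(out / "mapped_totals.tsv", sep="\t", index_label="sample_id", lineterminator="\n")
    io.write_circ_annotations(ds.circ_annotations, out / "circ_annotations.tsv")
    io.write_gmt(ds.gene_sets, out / "gene_sets.gmt")
    ds.truth.de_features.to_csv(out / "truth_de_features.tsv", sep="\t", index=False, lineterminator="\n")
    ds.truth.planted_pairs.to_csv(out / "truth_planted_pairs.tsv", sep="\t", index=False, lineterminator="\n")
    ds.truth.planted_triads.to_csv(out / "truth_planted_triads.tsv", sep="\t", index=False, lineterminator="\n")
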