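"""End-to-end orchestration: simulate -> normalize -> DE -> trends ->
targets -> enrichment -> triads -> export.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be re-entered individually (the CLI exposes
them as subcommands) and two runs with the same configuration and seed
produce byte-identical result trees.  All randomness fans out from one
master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from .cerna import CeRNATriad, assemble_triads, hub_stats, triads_to_frame
from .datagen import SimulationConfig, generate_dataset, write_dataset
from .enrichment import enrich
from .expression import (
    DEThresholds,
    call_de,
    comparison_label,
    compute_srpbm,
    default_thresholds,
    filter_highly_expressed,
    normalize_cpm,
    overlap_de,
)
from .targeting import predict_targets
from .trends import enumerate_profiles, profile_enrichment, stage_mean_matrix

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("cernapipe")

LAYER_FILES = {"miRNA": "counts_mirna.tsv", "mRNA": "counts_mrna.tsv", "circRNA": "counts_circ.tsv"}


@dataclass
class PipelineConfig:
    outdir: str = "results/run"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # existing dataset directory when simulate=False
    comparisons: list[tuple[str, str]] | None = None  # default: all stage pairs
    mirna_thresholds: DEThresholds = field(default_factory=lambda: default_thresholds("miRNA"))
    mrna_thresholds: DEThresholds = field(default_factory=lambda: default_thresholds("mRNA"))
    circ_thresholds: DEThresholds = field(default_factory=lambda: default_thresholds("circRNA"))
    score_threshold: float = 50.0
    energy_threshold: float = -20.0
    high_expr_threshold: float = 1000.0
    trend_c: int = 2
    trend_n_perm: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("score_threshold", "high_expr_threshold", "trend_c", "trend_n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.sim.rng_seed = derive_seed(self.rng_seed, 0)

    def thresholds_for(self, layer: str) -> DEThresholds:
        return {
            "miRNA": self.mirna_thresholds,
            "mRNA": self.mrna_thresholds,
            "circRNA": self.circ_thresholds,
        }[layer]


def derive_seed(master: int, stream: int) -> int:
    """Stable child seed < 2^31 from the master seed and a stream index."""
    return int(np.random.SeedSequence([master, stream]).generate_state(1)[0] % (2**31))


# --------------------------------------------------------------- loading

def _input_dir(cfg: PipelineConfig) -> Path:
    if cfg.simulate:
        return Path(cfg.outdir) / "inputs"
    if cfg.input_dir is None:
        raise ValueError("input_dir is required when simulate=False")
    p = Path(cfg.input_dir)
    if not p.exists():
        raise FileNotFoundError(f"input directory not found: {p}")
    return p


def _load_inputs(indir: Path):
    design_path = indir / "design.tsv"
    if not design_path.exists():
        raise FileNotFoundError(f"design file not found: {design_path}")
    design = io.read_design(design_path)
    counts = {
        layer: io.read_counts(indir / fname, design, layer=layer)
        for layer, fname in LAYER_FILES.items()
    }
    totals = pd.read_csv(indir / "mapped_totals.tsv", sep="\t", index_col=0)
    return design, counts, totals


def _normalized(cfg: PipelineConfig):
    indir = _input_dir(cfg)
    design, counts, totals = _load_inputs(indir)
    # per-million-mapped CPM: the count matrices cover a subset of each
    # library, so the mapped totals, not the matrix column sums, are the
    # denominators (SRPBM uses them by definition)
    norm = {
        "miRNA": normalize_cpm(counts["miRNA"], totals["miRNA"]),
        "mRNA": normalize_cpm(counts["mRNA"], totals["mRNA"]),
        "circRNA": compute_srpbm(counts["circRNA"], totals["circRNA"]),
    }
    return design, norm


def _comparisons(cfg: PipelineConfig, design: pd.DataFrame) -> list[tuple[str, str]]:
    if cfg.comparisons is not None:
        return [tuple(c) for c in cfg.comparisons]
    stages = io.stage_order_from_design(design)
    out = []
    for j in range(len(stages) - 1, 0, -1):
        for i in range(j):
            out.append((stages[j], stages[i]))
    return out


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> None:
    log.info("simulate: seed %d", cfg.sim.rng_seed)
    ds = generate_dataset(cfg.sim)
    write_dataset(ds, Path(cfg.outdir) / "inputs")


def stage_de(cfg: PipelineConfig) -> None:
    design, norm = _normalized(cfg)
    outdir = Path(cfg.outdir) / "de"
    outdir.mkdir(parents=True, exist_ok=True)
    comparisons = _comparisons(cfg, design)
    sig_sets: dict[str, dict[str, set]] = {layer: {} for layer in LAYER_FILES}
    for layer in LAYER_FILES:
        thresholds = cfg.thresholds_for(layer)
        for comp in comparisons:
            de = call_de(norm[layer], design, comp, thresholds)
            label = comparison_label(comp)
            de.to_csv(outdir / f"de_{layer}_{label}.tsv", sep="\t", lineterminator="\n")
            sig_sets[layer][label] = set(de.index[de["significant"]])
            log.info("de: %s %s -> %d significant", layer, label, de["significant"].sum())
    if len(comparisons) in (2, 3):
        venn = {
            layer: {"+".join(region): count for region, count in overlap_de(sets).items()}
            for layer, sets in sig_sets.items()
        }
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)
            fh.write("\n")
    high = filter_highly_expressed(norm["miRNA"], cfg.high_expr_threshold)
    pd.Series(sorted(high), name="mirna_id").to_csv(
        outdir / "highly_expressed_mirna.tsv", sep="\t", index=False, lineterminator="\n"
    )


def _sig_union(cfg: PipelineConfig, layer: str, design: pd.DataFrame, comparison: str | None = None) -> set:
    outdir = Path(cfg.outdir) / "de"
    labels = (
        [comparison]
        if comparison
        else [comparison_label(c) for c in _comparisons(cfg, design)]
    )
    out: set = set()
    for label in labels:
        de = pd.read_csv(outdir / f"de_{layer}_{label}.tsv", sep="\t", index_col=0)
        out |= set(de.index[de["significant"]])
    return out


def stage_trends(cfg: PipelineConfig) -> None:
    design, norm = _normalized(cfg)
    outdir = Path(cfg.outdir) / "trends"
    outdir.mkdir(parents=True, exist_ok=True)
    stages = io.stage_order_from_design(design)
    profiles = enumerate_profiles(len(stages), cfg.trend_c)
    pd.DataFrame(
        {
            "profile_id": [p.profile_id for p in profiles],
            "steps": [",".join(map(str, p.steps)) for p in profiles],
            "values": [",".join(map(str, p.values)) for p in profiles],
        }
    ).to_csv(outdir / "profiles.tsv", sep="\t", index=False, lineterminator="\n")
    for stream, layer in ((1, "miRNA"), (2, "circRNA")):
        de_feats = sorted(_sig_union(cfg, layer, design))
        if not de_feats:
            log.info("trends: %s has no DE features; skipping", layer)
            continue
        means = stage_mean_matrix(norm[layer], design, stages).loc[de_feats]
        result = profile_enrichment(
            means, profiles, n_perm=cfg.trend_n_perm, seed=derive_seed(cfg.rng_seed, stream)
        )
        result.to_csv(outdir / f"trend_enrichment_{layer}.tsv", sep="\t", lineterminator="\n")
        top = result[result["observed_count"] > 0].sort_values("p_value").head(1)
        if len(top):
            log.info(
                "trends: %s most significant profile steps (%s), p=%.4g",
                layer, top.iloc[0]["steps"], top.iloc[0]["p_value"],
            )


def stage_targets(cfg: PipelineConfig) -> None:
    indir = _input_dir(cfg)
    design, _counts, _totals = _load_inputs(indir)
    mirna_seqs = io.read_fasta(indir / "mirna.fa")
    utr_seqs = io.read_fasta(indir / "utr.fa")
    circ_seqs = io.read_fasta(indir / "circ.fa")
    outdir = Path(cfg.outdir) / "targets"
    outdir.mkdir(parents=True, exist_ok=True)
    sig_mirnas = _sig_union(cfg, "miRNA", design)
    scan = {m: mirna_seqs[m] for m in sorted(sig_mirnas) if m in mirna_seqs}
    frames = [
        predict_targets(scan, utr_seqs, "mRNA", cfg.score_threshold, cfg.energy_threshold),
        predict_targets(scan, circ_seqs, "circRNA", cfg.score_threshold, cfg.energy_threshold),
    ]
    pairs = pd.concat(frames, ignore_index=True)
    pairs.to_csv(outdir / "target_pairs.tsv", sep="\t", index=False, lineterminator="\n")
    log.info("targets: %d scanned pairs, %d pass score>%g & energy<%g",
             len(pairs), int(pairs["passes"].sum()), cfg.score_threshold, cfg.energy_threshold)


def _load_pairs(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(Path(cfg.outdir) / "targets" / "target_pairs.tsv", sep="\t")


def stage_enrich(cfg: PipelineConfig) -> None:
    indir = _input_dir(cfg)
    design, counts, _totals = _load_inputs(indir)
    gene_sets = io.read_gmt(indir / "gene_sets.gmt")
    ann = io.read_circ_annotations(indir / "circ_annotations.tsv")
    host = dict(zip(ann["circ_id"], ann["host_gene"]))
    pairs = _load_pairs(cfg)
    passing_mrna = pairs[(pairs["passes"]) & (pairs["layer"] == "mRNA")]
    universe = set(counts["mRNA"].feature_ids)
    outdir = Path(cfg.outdir) / "enrichment"
    outdir.mkdir(parents=True, exist_ok=True)
    for comp in _comparisons(cfg, design):
        label = comparison_label(comp)
        sig_mirna = _sig_union(cfg, "miRNA", design, label)
        targets = set(passing_mrna.loc[passing_mrna["mirna_id"].isin(sig_mirna), "target_id"])
        enrich(targets & universe, gene_sets, universe).to_csv(
            outdir / f"enrichment_mirna_targets_{label}.tsv", sep="\t", index=False, lineterminator="\n"
        )
        sig_circ = _sig_union(cfg, "circRNA", design, label)
        hosts = {host[c] for c in sig_circ if c in host}
        enrich(hosts & universe, gene_sets, universe).to_csv(
            outdir / f"enrichment_circ_hosts_{label}.tsv", sep="\t", index=False, lineterminator="\n"
        )


def stage_cerna(cfg: PipelineConfig) -> dict:
    indir = _input_dir(cfg)
    design, _counts, _totals = _load_inputs(indir)
    pairs = _load_pairs(cfg)
    de_dir = Path(cfg.outdir) / "de"
    outdir = Path(cfg.outdir) / "cerna"
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for comp in _comparisons(cfg, design):
        label = comparison_label(comp)
        de = {
            layer: pd.read_csv(de_dir / f"de_{layer}_{label}.tsv", sep="\t", index_col=0)
            for layer in LAYER_FILES
        }
        triads = assemble_triads(de["mRNA"], de["miRNA"], de["circRNA"], pairs)
        triads_to_frame(triads).to_csv(
            outdir / f"triads_{label}.tsv", sep="\t", index=False, lineterminator="\n"
        )
        io.export_network(pairs, triads, outdir / f"network_{label}.sif", "SIF")
        io.export_network(pairs, triads, outdir / f"network_{label}.graphml", "GraphML")
        hub_stats(pairs, triads).to_csv(
            outdir / f"hub_stats_{label}.tsv", sep="\t", index=False, lineterminator="\n"
        )
        modes = pd.Series([t.mode for t in triads])
        summary[label] = {
            "n_triads": len(triads),
            "n_down_up_down": int((modes == "down-up-down").sum()) if len(triads) else 0,
            "n_up_down_up": int((modes == "up-down-up").sum()) if len(triads) else 0,
        }
        log.info("cerna: %s -> %d triads (%s)", label, len(triads), summary[label])
    return summary


# ------------------------------------------------------------------ run

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write a machine-readable run report.

    Returns the report dict; identical config + seed reproduce the output
    tree byte for byte.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        stage_simulate(cfg)
    stage_de(cfg)
    stage_trends(cfg)
    stage_targets(cfg)
    stage_enrich(cfg)
    triad_summary = stage_cerna(cfg)

    design, _counts, _totals = _load_inputs(_input_dir(cfg))
    comparisons = [comparison_label(c) for c in _comparisons(cfg, design)]
    de_counts = {}
    for layer in LAYER_FILES:
        de_counts[layer] = {}
        for label in comparisons:
            de = pd.read_csv(out / "de" / f"de_{layer}_{label}.tsv", sep="\t", index_col=0)
            de_counts[layer][label] = int(de["significant"].sum())
    pairs = _load_pairs(cfg)
    report = {
        "seed": cfg.rng_seed,
        "comparisons": comparisons,
        "thresholds": {
            "mirna_p": cfg.mirna_thresholds.p_max,
            "mrna_p": cfg.mrna_thresholds.p_max,
            "mrna_lfc": cfg.mrna_thresholds.lfc_min,
            "circ_p": cfg.circ_thresholds.p_max,
            "circ_lfc": cfg.circ_thresholds.lfc_min,
            "score": cfg.score_threshold,
            "energy": cfg.energy_threshold,
            "high_expression": cfg.high_expr_threshold,
        },
        "n_significant": de_counts,
        "n_target_pairs_scanned": len(pairs),
        "n_target_pairs_passing": int(pairs["passes"].sum()),
        "triads": triad_summary,
        "versions": {"cernapipe": _package_version()},
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _package_version() -> str:
    from . import __version__

    return __version__
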