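"""Readers and writers for the formats the pipeline touches.

FASTA (via Biopython, canonicalized to uppercase RNA), counts/design/
annotation TSVs, GMT gene sets, and SIF/GraphML network export for
Cytoscape.  Readers reject malformed input with positional diagnostics;
writers are deterministic byte-for-byte given identical inputs.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import IUPAC_CODES, canonicalize_rna
from .expression import ExpressionMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_circ_annotations",
    "write_circ_annotations",
    "read_gmt",
    "write_gmt",
    "export_network",
    "stage_order_from_design",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Ordered {id: sequence}, uppercased, T->U (RNA internal standard)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"non-IUPAC character {ch!r} at position {i} of record "
                    f"{rec.id!r} in {path}"
                )
        records[rec.id] = canonicalize_rna(seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: dict[str, str], path) -> None:
    if not seqs:
        raise ValueError("refusing to write an empty FASTA")
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------- counts

def read_counts(path, design: pd.DataFrame, layer: str = "mRNA") -> ExpressionMatrix:
    """Raw count TSV (feature_id + one column per sample) as an
    ExpressionMatrix with columns reordered to the design's sample order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in design["sample_id"] if s not in df.columns]
    if missing:
        raise ValueError(f"count file {path} missing sample column(s) {missing}")
    df = df[list(design["sample_id"])]
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            i = int(bad.to_numpy().argmax())
            raise ValueError(
                f"non-numeric count at feature {df.index[i]!r}, sample {col!r} in {path}"
            )
        if (vals < 0).any():
            i = int((vals < 0).to_numpy().argmax())
            raise ValueError(
                f"negative count at feature {df.index[i]!r}, sample {col!r} in {path}"
            )
    return ExpressionMatrix(df.astype(float), units="raw", layer=layer)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data
    if matrix.units == "raw":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


# ---------------------------------------------------------------- design

def _stage_key(stage: str):
    digits = "".join(ch for ch in stage if ch.isdigit())
    return (int(digits) if digits else 0, stage)


def stage_order_from_design(design: pd.DataFrame) -> list[str]:
    """Stages ordered by their leading number (6M < 18M < 30M)."""
    return sorted(design["stage"].unique(), key=_stage_key)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    needed = {"sample_id", "stage", "replicate"}
    missing = needed - set(design.columns)
    if missing:
        raise ValueError(f"design {path} missing column(s) {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in {path}")
    order = sorted(design["stage"].unique(), key=_stage_key)
    design["stage"] = pd.Categorical(design["stage"], categories=order, ordered=True)
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design[["sample_id", "stage", "replicate"]].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ----------------------------------------------------- circRNA annotation

CIRC_COLUMNS = ["circ_id", "chrom", "start", "end", "strand", "host_gene"]


def read_circ_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"circ_id": str, "chrom": str})
    missing = set(CIRC_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation {path} missing column(s) {sorted(missing)}")
    bad = ann[(ann["start"] < 0) | (ann["start"] >= ann["end"])]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"invalid interval [{row['start']}, {row['end']}) for {row['circ_id']!r} "
            f"in {path} (0-based half-open, start < end required)"
        )
    bad_strand = ann[~ann["strand"].isin(["+", "-"])]
    if len(bad_strand):
        raise ValueError(
            f"invalid strand {bad_strand.iloc[0]['strand']!r} for "
            f"{bad_strand.iloc[0]['circ_id']!r} in {path}"
        )
    return ann[CIRC_COLUMNS]


def write_circ_annotations(ann: pd.DataFrame, path) -> None:
    ann[CIRC_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------------------ GMT

def read_gmt(path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {lineno} in {path} has {len(parts)} fields; "
                    "expected set_id, description, >= 1 gene"
                )
            set_id = parts[0]
            if set_id in sets:
                raise ValueError(f"duplicate gene set id {set_id!r} at line {lineno}")
            sets[set_id] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict[str, set], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(gene_sets):
            desc = (descriptions or {}).get(set_id, "na")
            genes = "\t".join(sorted(gene_sets[set_id]))
            fh.write(f"{set_id}\t{desc}\t{genes}\n")


# -------------------------------------------------------------- networks

def export_network(pairs: pd.DataFrame, triads, path, dialect: str = "SIF") -> None:
    """Write the targeting/ceRNA network for Cytoscape.

    SIF: "source<TAB>relation<TAB>target" rows with relations ``targets``
    (miRNA -> mRNA/circRNA) and ``cerna`` (mRNA - circRNA partners in a
    triad).  GraphML: nodes carry ``layer`` and ``direction`` attributes.
    Deterministic node and edge order.
    """
    if dialect not in ("SIF", "GraphML"):
        raise ValueError(f"unknown network dialect {dialect!r}")

    target_edges = set()
    if pairs is not None and len(pairs):
        passing = pairs[pairs["passes"]] if "passes" in pairs.columns else pairs
        for row in passing.itertuples():
            target_edges.add((row.mirna_id, row.target_id, row.layer))
    cerna_edges = set()
    directions: dict[str, str] = {}
    for t in triads or ():
        target_edges.add((t.mirna_id, t.mrna_id, "mRNA"))
        target_edges.add((t.mirna_id, t.circ_id, "circRNA"))
        cerna_edges.add((t.mrna_id, t.circ_id))
        g_dir = t.mode.split("-")[0]
        m_dir = t.mode.split("-")[1]
        directions.update({t.mrna_id: g_dir, t.circ_id: g_dir, t.mirna_id: m_dir})

    if dialect == "SIF":
        with open(path, "w") as fh:
            for mirna, target, _layer in sorted(target_edges):
                fh.write(f"{mirna}\ttargets\t{target}\n")
            for g, c in sorted(cerna_edges):
                fh.write(f"{g}\tcerna\t{c}\n")
        return

    G = nx.DiGraph()
    nodes: dict[str, str] = {}
    for mirna, target, layer in sorted(target_edges):
        nodes[mirna] = "miRNA"
        nodes[target] = layer
    for name in sorted(nodes):
        G.add_node(name, layer=nodes[name], direction=directions.get(name, "none"))
    for mirna, target, _layer in sorted(target_edges):
        G.add_edge(mirna, target, relation="targets")
    for g, c in sorted(cerna_edges):
        G.add_edge(g, c, relation="cerna")
    nx.write_graphml(G, path)
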