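"""Tabular and sequence I/O with cross-validation.

All tabular artifacts are tab-delimited UTF-8 text with a header row; the
probe-set id is always the first column of matrix-like files.  Expression
values are asserted (not autodetected) to be log2 scale.  Floats are
written at full precision so every format round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import MotifHit

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_presence_tsv",
    "write_presence_tsv",
    "read_probe_map_tsv",
    "write_probe_map_tsv",
    "read_dataset",
    "write_dataset",
    "read_fasta",
    "write_fasta",
    "write_motif_hits_tsv",
    "read_motif_hits_tsv",
    "write_results",
]


def _read_indexed_tsv(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = index_name
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {index_name}s in {path}: {dups[:10]}")
    return df


def read_expression_tsv(path) -> pd.DataFrame:
    """Probe set x sample log2 expression matrix."""
    df = _read_indexed_tsv(path, "probe_set_id")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        raise ValueError(f"expression matrix {path} has missing/non-finite values")
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("probe_set_id").to_csv(path, sep="\t", float_format="%.17g")


def read_design_tsv(path) -> pd.Series:
    """Two-column sample design: sample_id, timepoint_h (0 = control)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns[:2]) != ["sample_id", "timepoint_h"]:
        raise ValueError(
            f"design {path} must have columns sample_id, timepoint_h; "
            f"got {list(df.columns)}"
        )
    design = df.set_index("sample_id")["timepoint_h"].astype(int)
    if (design == 0).sum() < 2:
        raise ValueError("design must label >=2 samples as 0 h controls")
    return design


def write_design_tsv(design: pd.Series, path) -> None:
    design.rename("timepoint_h").rename_axis("sample_id").to_csv(path, sep="\t")


def read_presence_tsv(path) -> pd.DataFrame:
    """Binary presence-flag matrix (MAS5-style present calls)."""
    df = _read_indexed_tsv(path, "probe_set_id")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = sorted(set(values.ravel()) - {0, 1})
        raise ValueError(f"presence matrix {path} has non-binary values: {bad[:5]}")
    return df.astype(int)


def write_presence_tsv(presence: pd.DataFrame, path) -> None:
    presence.rename_axis("probe_set_id").to_csv(path, sep="\t")


def read_probe_map_tsv(path) -> pd.DataFrame:
    """Probe set -> gene mapping, with an optional transcript/exon tag."""
    df = _read_indexed_tsv(path, "probe_set_id")
    if "gene_id" not in df.columns:
        raise ValueError(f"probe map {path} needs a gene_id column")
    return df


def write_probe_map_tsv(probe_map: pd.DataFrame, path) -> None:
    probe_map.rename_axis("probe_set_id").to_csv(path, sep="\t")


def read_dataset(matrix_path, design_path, presence_path, map_path):
    """Load and cross-validate the full input bundle.

    Checks that the design labels exactly the matrix columns, the presence
    matrix shares the expression matrix's shape and ids, and every probe
    set has a gene mapping.  Row/column order is preserved from file.
    """
    expr = read_expression_tsv(matrix_path)
    design = read_design_tsv(design_path)
    presence = read_presence_tsv(presence_path)
    probe_map = read_probe_map_tsv(map_path)

    missing = [c for c in expr.columns if c not in design.index]
    extra = [s for s in design.index if s not in expr.columns]
    if missing or extra:
        raise ValueError(
            f"sample ids disagree between matrix and design; "
            f"unlabelled columns: {missing}; design-only samples: {extra}"
        )
    design = design.reindex(expr.columns)
    if not expr.index.equals(presence.index) or list(expr.columns) != list(
        presence.columns
    ):
        raise ValueError("presence matrix ids/shape differ from expression matrix")
    unmapped = expr.index.difference(probe_map.index)
    if len(unmapped):
        raise ValueError(f"probe sets missing from map: {sorted(unmapped)[:10]}")
    return expr, design, presence, probe_map


def write_dataset(dataset, out_dir) -> dict[str, str]:
    """Write a simulated dataset's five TSVs; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "presence": out / "presence.tsv",
        "probe_map": out / "probe_map.tsv",
        "truth_probesets": out / "truth_probesets.tsv",
        "truth_genes": out / "truth_genes.tsv",
    }
    write_expression_tsv(dataset.expression, paths["expression"])
    write_design_tsv(dataset.design, paths["design"])
    write_presence_tsv(dataset.presence, paths["presence"])
    write_probe_map_tsv(dataset.probe_map, paths["probe_map"])
    dataset.truth.probesets.to_csv(paths["truth_probesets"], sep="\t")
    dataset.truth.genes.to_csv(paths["truth_genes"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def read_fasta(path) -> list[tuple[str, str]]:
    """(sequence_id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records),
        str(path),
        "fasta",
    )


_HIT_COLUMNS = ["sequence_id", "start", "end", "class_name", "matched_text"]


def write_motif_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    """BED-like hit table: sequence_id, start, end, class, matched text."""
    pd.DataFrame(
        [(h.sequence_id, h.start, h.end, h.class_name, h.matched_text) for h in hits],
        columns=_HIT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_motif_hits_tsv(path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "matched_text": str})
    return [
        MotifHit(r.sequence_id, r.class_name, int(r.start), int(r.end), r.matched_text)
        for r in df.itertuples()
    ]


def write_results(
    out_dir,
    calls: pd.DataFrame | None = None,
    clusters: pd.Series | None = None,
    cluster_summary: pd.DataFrame | None = None,
    discordance: pd.DataFrame | None = None,
    motif_hits: Iterable[MotifHit] | None = None,
    run_info: dict | None = None,
) -> dict[str, str]:
    """Write any subset of result components plus a JSON run summary.

    The run summary records the parameters, seeds and per-component row
    counts so a run is auditable from its output directory alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    counts: dict[str, int] = {}
    if calls is not None:
        p = out / "induction_calls.tsv"
        calls.rename_axis("probe_set_id").to_csv(p, sep="\t", float_format="%.17g")
        paths["calls"], counts["calls"] = str(p), len(calls)
    if clusters is not None:
        p = out / "cluster_assignments.tsv"
        clusters.rename("cluster_id").rename_axis("probe_set_id").to_csv(p, sep="\t")
        paths["clusters"], counts["clusters"] = str(p), len(clusters)
    if cluster_summary is not None:
        p = out / "cluster_summary.tsv"
        cluster_summary.to_csv(p, sep="\t", index=False)
        paths["cluster_summary"] = str(p)
        counts["cluster_summary"] = len(cluster_summary)
    if discordance is not None:
        p = out / "discordance_report.tsv"
        discordance.rename_axis("gene_id").to_csv(p, sep="\t")
        paths["discordance"], counts["discordance"] = str(p), len(discordance)
    if motif_hits is not None:
        hits = list(motif_hits)
        p = out / "motif_hits.tsv"
        write_motif_hits_tsv(hits, p)
        paths["motif_hits"], counts["motif_hits"] = str(p), len(hits)
    summary = {"components": counts, **(run_info or {})}
    summary_path = out / "run_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    paths["run_summary"] = str(summary_path)
    return paths
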