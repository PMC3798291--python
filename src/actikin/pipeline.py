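"""End-to-end orchestration: error model -> detection -> FDR -> clustering
-> discordance, with a run manifest.

The pipeline consumes either a simulated dataset or the four input TSVs
(expression, design, presence, probe map), executes each analysis stage in
order, writes every artifact as plain TSV/JSON under the output directory
and records parameters, derived per-stage seeds and per-stage counts in
``manifest.json``.  All randomness fans out from one global seed, so an
identical config reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import build_profiles, cluster_profiles, summarize_clusters
from .detection import (
    DetectionParams,
    call_induced,
    compute_logfc,
    estimate_fdr_by_permutation,
)
from .discordance import candidate_alt_transcripts, classify_gene_probesets
from .error_model import compute_z, fit_error_model
from .io import read_dataset, write_dataset, write_results
from .simulate import SimConfig, simulate_timecourse

__all__ = ["RunConfig", "run_full"]

log = logging.getLogger("actikin")

# fixed offsets fan the global seed out to the stochastic stages
_FDR_SEED_OFFSET = 10
_CLUSTER_SEED_OFFSET = 20


@dataclass
class RunConfig:
    """Everything a full run needs; either simulate or point at input TSVs."""

    out_dir: str = "actikin_out"
    seed: int = 0
    simulate: SimConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    presence_path: str | None = None
    map_path: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    run_fdr: bool = True
    cluster_k: int = 5
    cluster_restarts: int = 25
    loess_span: float = 0.75
    loess_degree: int = 2

    def validate(self) -> None:
        file_inputs = [self.matrix_path, self.design_path, self.presence_path,
                       self.map_path]
        if self.simulate is None and not all(file_inputs):
            raise ValueError(
                "provide either a simulation config or all four input paths "
                "(matrix, design, presence, map)"
            )


def run_full(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "simulate": config.seed,
            "fdr": config.seed + _FDR_SEED_OFFSET,
            "cluster": config.seed + _CLUSTER_SEED_OFFSET,
        },
        "parameters": {
            "z_threshold": config.detection.z_threshold,
            "min_present_arrays": config.detection.min_present_arrays,
            "two_sided": config.detection.two_sided,
            "n_permutations": config.detection.n_permutations,
            "cluster_k": config.cluster_k,
            "cluster_restarts": config.cluster_restarts,
            "loess_span": config.loess_span,
            "loess_degree": config.loess_degree,
        },
        "counts": {},
        "stages": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        if config.simulate is not None:
            stage("simulate")
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            dataset = simulate_timecourse(sim_cfg)
            write_dataset(dataset, out / "data")
            truth = dataset.truth
        else:
            stage("load")
            dataset_tuple = read_dataset(
                config.matrix_path, config.design_path,
                config.presence_path, config.map_path,
            )
            from .simulate import SimulatedDataset

            dataset = SimulatedDataset(*dataset_tuple, None)
            truth = None
        expr, design, presence, probe_map = (
            dataset.expression, dataset.design, dataset.presence, dataset.probe_map,
        )
        manifest["counts"]["probe_sets"] = int(expr.shape[0])
        manifest["counts"]["samples"] = int(expr.shape[1])

        stage("error_model")
        model = fit_error_model(
            expr, design, span=config.loess_span, degree=config.loess_degree
        )
        model.to_json(out / "error_model.json")

        stage("detection")
        zmat = compute_z(expr, design, model)
        calls = call_induced(zmat, presence, config.detection, probe_map=probe_map)
        n_induced = int(calls["induced"].sum())
        manifest["counts"]["passing_presence"] = int(
            (calls["present_count"] >= config.detection.min_present_arrays).sum()
        )
        manifest["counts"]["induced_probe_sets"] = n_induced
        manifest["counts"]["induced_genes"] = int(
            calls.loc[calls["induced"], "gene_id"].nunique()
        )
        log.info("induced probe sets: %d / %d", n_induced, len(calls))

        fdr_est = None
        if config.run_fdr:
            stage("fdr")
            fdr_params = dataclasses.replace(
                config.detection, seed=config.seed + _FDR_SEED_OFFSET
            )
            fdr_est = estimate_fdr_by_permutation(expr, design, presence, fdr_params)
            fdr_est.to_json(out / "fdr.json")
            manifest["counts"]["fdr_observed_positives"] = fdr_est.observed_positives
            manifest["fdr"] = fdr_est.fdr
            log.info("permutation FDR estimate: %.4f", fdr_est.fdr)

        assignments = None
        summary = None
        if n_induced >= config.cluster_k:
            stage("clustering")
            logfc = compute_logfc(expr, design)
            profiles = build_profiles(logfc, calls.index[calls["induced"]])
            cmodel = cluster_profiles(
                profiles,
                k=config.cluster_k,
                seed=config.seed + _CLUSTER_SEED_OFFSET,
                n_restarts=config.cluster_restarts,
            )
            assignments = cmodel.assignments
            summary = summarize_clusters(cmodel, profiles)
            manifest["counts"]["cluster_sizes"] = (
                assignments.value_counts().sort_index().to_dict()
            )
        else:
            log.info(
                "clustering skipped: %d induced probe sets < k=%d",
                n_induced, config.cluster_k,
            )
            manifest["counts"]["cluster_sizes"] = {}

        stage("discordance")
        report = classify_gene_probesets(
            calls.drop(columns=["gene_id"]),
            probe_map,
            min_assessable_present=config.detection.min_present_arrays,
            cluster_assignments=assignments,
        )
        candidates = candidate_alt_transcripts(
            report, kinetic_filter=assignments is not None
        )
        manifest["counts"]["discordant_genes"] = int(
            (report.genes["status"] == "discordant").sum()
        )

        stage("write")
        write_results(
            out,
            calls=calls,
            clusters=assignments,
            cluster_summary=summary,
            discordance=report.genes,
            run_info={"seed": config.seed, **manifest["parameters"]},
        )
        candidates.rename_axis("gene_id").to_csv(
            out / "alt_transcript_candidates.tsv", sep="\t"
        )
        if truth is not None:
            manifest["counts"]["true_induced_probe_sets"] = int(
                truth.probesets["induced"].sum()
            )
    except Exception as exc:  # annotate with the failing stage
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
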