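"""Probe-set discordance within genes: candidate exon / 3'-UTR switches.

On expression arrays a gene is often interrogated by several probe sets
covering different transcript regions.  When some of a gene's probe sets
are induced by activity while others are flat — the pattern seen for
Zwint, where 4 of 6 probe sets responded and the silent 2 covered the
alternative terminal exon — the gene is a candidate for an
activity-dependent exon switch or alternative 3'-UTR selection.  This
module tallies induction calls per gene and flags such discordant genes,
optionally adding a kinetic signal (induced probe sets falling in
different clusters, the Homer1/Ania-3-style pattern).
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

__all__ = ["DiscordanceReport", "classify_gene_probesets", "candidate_alt_transcripts"]

STATUS_CONC_INDUCED = "concordant_induced"
STATUS_CONC_UNINDUCED = "concordant_uninduced"
STATUS_DISCORDANT = "discordant"
STATUS_UNASSESSABLE = "unassessable"


class DiscordanceReport(NamedTuple):
    """Per-gene tallies plus per-probe-set detail."""

    genes: pd.DataFrame   # index gene_id
    detail: pd.DataFrame  # index probe_set_id


def classify_gene_probesets(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    min_assessable_present: int = 3,
    cluster_assignments: pd.Series | None = None,
) -> DiscordanceReport:
    """Partition genes into concordant / discordant / unassessable.

    Probe sets present on fewer than ``min_assessable_present`` arrays are
    unassessable (a never-expressed variant's probe set is no evidence of
    non-induction) and excluded from the induced/uninduced dichotomy.  A
    gene is discordant iff it has at least one induced and one assessable
    non-induced probe set.
    """
    missing = calls.index.difference(probe_map.index)
    if len(missing):
        raise KeyError(
            f"probe sets missing from the gene map: {sorted(missing)[:10]}"
        )
    detail = calls.copy()
    detail["gene_id"] = probe_map["gene_id"].reindex(detail.index)
    detail["assessable"] = detail["present_count"] >= min_assessable_present
    if cluster_assignments is not None:
        detail["cluster_id"] = cluster_assignments.reindex(detail.index)

    rows = []
    for gene_id, grp in detail.groupby("gene_id", sort=True):
        assessable = grp[grp["assessable"]]
        n_induced = int(assessable["induced"].sum())
        n_not = int((~assessable["induced"]).sum())
        n_unass = int((~grp["assessable"]).sum())
        if n_induced >= 1 and n_not >= 1:
            status = STATUS_DISCORDANT
        elif n_induced >= 1:
            status = STATUS_CONC_INDUCED
        elif n_not >= 1:
            status = STATUS_CONC_UNINDUCED
        else:
            status = STATUS_UNASSESSABLE
        induced_grp = grp[grp["induced"] & grp["assessable"]]
        if len(induced_grp):
            top = induced_grp["max_z"].idxmax()
            max_z = float(induced_grp["max_z"].max())
        else:
            top = grp["max_z"].idxmax() if len(grp) else None
            max_z = float(grp["max_z"].max()) if len(grp) else float("nan")
        rows.append(
            {
                "gene_id": gene_id,
                "n_probe_sets": len(grp),
                "n_induced": n_induced,
                "n_not_induced": n_not,
                "n_unassessable": n_unass,
                "status": status,
                "top_probe_set": top,
                "max_z": max_z,
            }
        )
    genes = pd.DataFrame(rows).set_index("gene_id")
    return DiscordanceReport(genes=genes, detail=detail)


def candidate_alt_transcripts(
    report: DiscordanceReport, kinetic_filter: bool = False
) -> pd.DataFrame:
    """Discordant genes ranked by max induced Z (descending).

    With ``kinetic_filter=True`` (requires cluster ids in the report
    detail) a ``kinetic_heterogeneous`` column flags genes whose induced
    probe sets fall into more than one kinetic cluster — variants that are
    not only differentially included but also differ in their induction
    time course.
    """
    cand = report.genes[report.genes["status"] == STATUS_DISCORDANT].copy()
    cand = cand.sort_values("max_z", ascending=False)
    if kinetic_filter:
        if "cluster_id" not in report.detail.columns:
            raise ValueError(
                "kinetic_filter requires cluster assignments in the report"
            )
        het = {}
        for gene_id in cand.index:
            grp = report.detail[
                (report.detail["gene_id"] == gene_id) & report.detail["induced"]
            ]
            het[gene_id] = grp["cluster_id"].dropna().nunique() > 1
        cand["kinetic_heterogeneous"] = pd.Series(het)
    return cand
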