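#!/usr/bin/env python
"""Flag genes whose probe sets disagree in induction status.

Genes with at least one induced and one assessable-but-flat probe set are
candidate activity-dependent exon switches / alternative 3'-UTR users
(the 4-induced-of-6 Zwint pattern).  Candidates are ranked by max induced
Z; genes whose induced probe sets fall in different kinetic clusters are
additionally marked as kinetically heterogeneous.  Scores recovery against
the planted discordant genes.
"""

from pathlib import Path

import pandas as pd

from actikin.discordance import (
    STATUS_DISCORDANT,
    candidate_alt_transcripts,
    classify_gene_probesets,
)
from actikin.io import read_probe_map_tsv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    calls = pd.read_csv(RESULTS / "induction_calls.tsv", sep="\t", index_col=0)
    probe_map = read_probe_map_tsv(RESULTS / "data" / "probe_map.tsv")
    clusters = pd.read_csv(RESULTS / "cluster_assignments.tsv", sep="\t",
                           index_col=0)["cluster_id"]
    report = classify_gene_probesets(
        calls.drop(columns=["gene_id"]), probe_map,
        min_assessable_present=3, cluster_assignments=clusters,
    )
    report.genes.to_csv(RESULTS / "discordance_report.tsv", sep="\t")
    candidates = candidate_alt_transcripts(report, kinetic_filter=True)
    candidates.rename_axis("gene_id").to_csv(
        RESULTS / "alt_transcript_candidates.tsv", sep="\t")

    print(report.genes["status"].value_counts().to_string())
    truth = pd.read_csv(RESULTS / "data" / "truth_genes.tsv", sep="\t",
                        index_col=0)
    planted = set(truth.index[truth["discordant"]])
    flagged = set(report.genes.index[report.genes["status"] == STATUS_DISCORDANT])
    if planted:
        sens = len(planted & flagged) / len(planted)
        print(f"planted discordant genes recovered: {sens:.2%} "
              f"({len(planted & flagged)}/{len(planted)}); "
              f"false flags: {len(flagged - planted)}")
    n_het = int(candidates.get("kinetic_heterogeneous", pd.Series(dtype=bool)).sum())
    print(f"kinetically heterogeneous candidates: {n_het}")
    print("wrote:", RESULTS / "discordance_report.tsv", "and",
          RESULTS / "alt_transcript_candidates.tsv")


if __name__ == "__main__":
    main()
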