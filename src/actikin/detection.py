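"""Induced-gene calling, permutation FDR and cross-dataset comparison.

A probe set is called induced when its Z value exceeds the threshold at any
post-stimulus timepoint AND it carries a presence flag on at least
``min_present_arrays`` arrays.  The false discovery rate of this compound
rule is estimated non-parametrically by permuting the untreated arrays:
each permutation splits the control arrays into a pseudo-control and a
pseudo-treated group, refits the error model on the pseudo-controls, and
counts probe sets the rule would call; FDR = mean null count / observed
count.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .error_model import ErrorModel, ZMatrix, compute_z, control_samples, fit_error_model

__all__ = [
    "DetectionParams",
    "FdrEstimate",
    "call_induced",
    "estimate_fdr_by_permutation",
    "compute_logfc",
    "crossdataset_correlation",
]


@dataclass
class DetectionParams:
    """Thresholds of the induction rule and the permutation design.

    ``two_sided=False`` calls induction only (Z > threshold); the two-sided
    mode uses |Z| and additionally captures downregulation.
    """

    z_threshold: float = 5.0
    min_present_arrays: int = 3
    two_sided: bool = False
    n_permutations: int = 25
    seed: int = 0

    def validate(self, n_samples: int | None = None) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.min_present_arrays < 0:
            raise ValueError("min_present_arrays must be >= 0")
        if n_samples is not None and self.min_present_arrays > n_samples:
            raise ValueError(
                f"min_present_arrays={self.min_present_arrays} exceeds "
                f"{n_samples} samples"
            )


def call_induced(
    z: ZMatrix,
    presence: pd.DataFrame,
    params: DetectionParams | None = None,
    probe_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One call per probe set under the conjunctive induction rule.

    Returns a table with per-timepoint Z, max Z, the argmax (peak)
    timepoint, the presence count over all arrays and the induced flag.
    """
    params = params or DetectionParams()
    params.validate(n_samples=presence.shape[1])
    if not z.z.index.equals(presence.index):
        raise ValueError("Z matrix and presence matrix index differ")
    zval = z.z.abs() if params.two_sided else z.z
    max_z = zval.max(axis=1)
    peak = zval.idxmax(axis=1)
    present_count = presence.sum(axis=1)
    induced = (max_z > params.z_threshold) & (
        present_count >= params.min_present_arrays
    )
    calls = pd.DataFrame(
        {
            **{f"Z_{t}h": z.z[t] for t in z.timepoints},
            "max_z": max_z,
            "peak_timepoint": peak,
            "present_count": present_count,
            "induced": induced,
        }
    )
    if probe_map is not None:
        calls.insert(0, "gene_id", probe_map["gene_id"].reindex(calls.index))
    calls.index.name = "probe_set_id"
    return calls


@dataclass
class FdrEstimate:
    """Permutation-based FDR of the induction procedure."""

    observed_positives: int
    null_positive_counts: list[int]
    fdr: float
    seed: int
    n_permutations: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_permutations = len(self.null_positive_counts)
        if self.fdr < 0:
            raise ValueError("fdr must be nonnegative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "observed_positives": self.observed_positives,
                    "null_positive_counts": self.null_positive_counts,
                    "fdr": self.fdr,
                    "seed": self.seed,
                    "n_permutations": self.n_permutations,
                },
                fh,
                indent=1,
            )


def _control_splits(
    controls: list, size: int, n_permutations: int, rng: np.random.Generator
) -> list[tuple]:
    """Random pseudo-treated subsets of the control arrays.

    Distinct subsets are drawn without replacement as long as they last
    (e.g. C(6,3)=20 for the default design); further draws repeat.
    """
    all_splits = list(itertools.combinations(controls, size))
    order = rng.permutation(len(all_splits))
    splits = [all_splits[i] for i in order[: min(n_permutations, len(all_splits))]]
    while len(splits) < n_permutations:
        splits.append(all_splits[int(rng.integers(len(all_splits)))])
    return splits


def estimate_fdr_by_permutation(
    expr: pd.DataFrame,
    design: pd.Series,
    presence: pd.DataFrame,
    params: DetectionParams | None = None,
    pseudo_treated_size: int | None = None,
) -> FdrEstimate:
    """Estimate the induction procedure's FDR from control permutations.

    Each permutation designates ``pseudo_treated_size`` control arrays
    (default: the real design's replicates per timepoint) as a fake
    timepoint, refits the error model on the remaining controls, computes Z
    for the fake timepoint and counts probe sets passing the induction rule
    (the any-timepoint rule reduces to this single pseudo-timepoint).
    """
    params = params or DetectionParams()
    controls = list(control_samples(design))
    if pseudo_treated_size is not None:
        size = pseudo_treated_size
    else:
        reps = design[design != 0].value_counts()
        size = int(reps.mode().iloc[0]) if len(reps) else 3
    if len(controls) - size < 2:
        raise ValueError(
            f"{len(controls)} controls cannot support {size}-array "
            "pseudo-treated splits (needs >=2 pseudo-controls)"
        )

    # observed positives from the real design
    model = fit_error_model(expr, design)
    observed = int(call_induced(compute_z(expr, design, model), presence, params)
                   ["induced"].sum())

    rng = np.random.default_rng(params.seed)
    null_counts: list[int] = []
    for split in _control_splits(controls, size, params.n_permutations, rng):
        pseudo_treated = list(split)
        pseudo_controls = [c for c in controls if c not in pseudo_treated]
        sub = expr[pseudo_controls + pseudo_treated]
        pseudo_design = pd.Series(
            [0] * len(pseudo_controls) + [1] * len(pseudo_treated),
            index=sub.columns, name="timepoint_h",
        )
        pmodel = fit_error_model(sub, pseudo_design)
        pz = compute_z(sub, pseudo_design, pmodel)
        pcalls = call_induced(pz, presence, params)
        null_counts.append(int(pcalls["induced"].sum()))

    if observed == 0:
        warnings.warn("no observed positives; FDR reported as 0", stacklevel=2)
        fdr = 0.0
    else:
        fdr = float(np.mean(null_counts)) / observed
    return FdrEstimate(
        observed_positives=observed,
        null_positive_counts=null_counts,
        fdr=fdr,
        seed=params.seed,
    )


def compute_logfc(expr: pd.DataFrame, design: pd.Series) -> pd.DataFrame:
    """Per-probe-set log2 fold change (timepoint mean minus control mean)."""
    controls = control_samples(design)
    if len(controls) < 1:
        raise ValueError("design has no 0 h control samples")
    m0 = expr[controls].mean(axis=1)
    out = {}
    for t in sorted(int(t) for t in design.unique() if t != 0):
        cols = design.index[design == t]
        out[t] = expr[cols].mean(axis=1) - m0
    return pd.DataFrame(out)


def crossdataset_correlation(
    logfc_a: pd.DataFrame,
    logfc_b: pd.DataFrame,
    shared_ids,
    timepoint: int,
) -> float:
    """Pearson correlation of two datasets' log fold changes.

    Restricted to the shared probe-set ids at one timepoint — the standard
    check that induction replicates across independent experiments (e.g.
    mouse strains).
    """
    shared = pd.Index(shared_ids)
    if len(shared) < 3:
        raise ValueError("need >=3 shared ids for a correlation")
    a = logfc_a.loc[shared, timepoint].to_numpy()
    b = logfc_b.loc[shared, timepoint].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a log-FC vector; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)
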