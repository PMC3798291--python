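"""Synthetic replicated microarray time courses with known ground truth.

The generator emulates the structure of a seizure time-course experiment on
expression arrays: 6 control (0 h) arrays plus 3 biological replicates at
each of 1, 4, 8 and 24 h, log2-scale probe-set expression with
mean-dependent Gaussian noise, MAS5-style binary presence flags, genes
carried by several probe sets, and five kinetic induction archetypes
(fast-sustained, fast-transient, late-peaking, biphasic, slow-rising).
Every simulated probe set comes with its generating truth so detection,
clustering and discordance calls can be scored against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .motifs import DEFAULT_MOTIFS, MotifDef, MotifHit, scan_sequence

__all__ = [
    "SdCurve",
    "KineticArchetype",
    "ARCHETYPES",
    "SimConfig",
    "TruthTable",
    "SimulatedDataset",
    "SyntheticUtrSet",
    "simulate_timecourse",
    "simulate_from_truth",
    "simulate_null",
    "generate_utr_set",
]


@dataclass(frozen=True)
class SdCurve:
    """Monotone-decreasing replicate-SD curve ``sd = a + b * exp(-c * mean)``.

    Defaults span roughly 0.5 log2 units of noise at the bottom of the RMA
    expression range down to ~0.1 at the top, the qualitative mean-variance
    shape of RMA-summarised arrays.
    """

    a: float = 0.1
    b: float = 1.5
    c: float = 0.35

    def __call__(self, mean):
        return self.a + self.b * np.exp(-self.c * np.asarray(mean, dtype=float))


@dataclass(frozen=True)
class KineticArchetype:
    """One of five temporal induction shapes, peak-normalised to 1."""

    id: int
    name: str
    profile: tuple[float, ...]  # relative log2 induction at each timepoint


#: The five archetypes, ordered as the analysis orders its clusters:
#: peak time ascending, then sustained before transient.
ARCHETYPES: tuple[KineticArchetype, ...] = (
    KineticArchetype(1, "fast-sustained", (1.00, 0.85, 0.60, 0.20)),
    KineticArchetype(2, "fast-transient", (1.00, 0.45, 0.15, 0.05)),
    KineticArchetype(3, "late-peak-8h", (0.25, 0.60, 1.00, 0.35)),
    KineticArchetype(4, "biphasic-1h-24h", (0.90, 0.30, 0.45, 1.00)),
    KineticArchetype(5, "slow-rising-24h", (0.15, 0.35, 0.60, 1.00)),
)


@dataclass
class SimConfig:
    """Design and noise parameters of the simulated study."""

    n_genes: int = 2000
    frac_induced: float = 0.2
    archetype_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    n_controls: int = 6
    replicates_per_timepoint: int = 3
    timepoints_h: tuple[int, ...] = (1, 4, 8, 24)
    baseline_mean_range: tuple[float, float] = (4.0, 14.0)
    sd_curve: Callable = field(default_factory=SdCurve)
    effect_size_z_range: tuple[float, float] = (8.0, 15.0)
    multi_probeset_frac: float = 0.2
    max_probesets_per_gene: int = 7
    discordant_frac: float = 0.1
    presence_midpoint: float = 2.5   # log2 expression of 50% presence
    presence_scale: float = 0.5      # logistic scale, log2 units
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_induced", "multi_probeset_frac", "discordant_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.archetype_weights) != len(ARCHETYPES):
            raise ValueError("archetype_weights must have 5 entries")
        w = np.asarray(self.archetype_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("archetype_weights must be nonnegative and sum to 1")
        tps = np.asarray(self.timepoints_h)
        if not (np.diff(tps) > 0).all():
            raise ValueError("timepoints_h must be strictly increasing")
        lo, hi = self.baseline_mean_range
        grid = np.linspace(lo, hi, 64)
        if not (np.asarray(self.sd_curve(grid)) > 0).all():
            raise ValueError("sd_curve must be strictly positive over baseline_mean_range")
        if self.n_controls < 2 or self.replicates_per_timepoint < 1:
            raise ValueError("need >=2 controls and >=1 replicate per timepoint")


@dataclass
class TruthTable:
    """Generating truth: one row per probe set plus a per-gene table."""

    probesets: pd.DataFrame  # index probe_set_id
    genes: pd.DataFrame      # index gene_id
    timepoints_h: tuple[int, ...]

    def lfc_columns(self) -> list[str]:
        return [f"lfc_{t}h" for t in self.timepoints_h]


class SimulatedDataset(NamedTuple):
    expression: pd.DataFrame
    design: pd.Series
    presence: pd.DataFrame
    probe_map: pd.DataFrame
    truth: TruthTable


def _make_truth(config: SimConfig, rng: np.random.Generator) -> TruthTable:
    """Draw gene/probe-set structure, induction status and effect sizes."""
    n = config.n_genes
    gene_ids = np.array([f"gene{i:05d}" for i in range(n)])
    n_ps = np.ones(n, dtype=int)
    n_multi = int(round(config.multi_probeset_frac * n))
    multi_idx = rng.choice(n, size=n_multi, replace=False)
    n_ps[multi_idx] = rng.integers(2, config.max_probesets_per_gene + 1, size=n_multi)

    n_induced = int(round(config.frac_induced * n))
    induced_gene = np.zeros(n, dtype=bool)
    induced_gene[rng.choice(n, size=n_induced, replace=False)] = True
    archetype = np.zeros(n, dtype=int)
    archetype[induced_gene] = rng.choice(
        [a.id for a in ARCHETYPES], size=n_induced, p=config.archetype_weights
    )
    z_lo, z_hi = config.effect_size_z_range
    z_target_gene = np.where(induced_gene, rng.uniform(z_lo, z_hi, size=n), 0.0)

    # discordant genes: induced, multi-probe-set, a random nonempty proper
    # subset of their probe sets receives zero induction
    eligible = np.flatnonzero(induced_gene & (n_ps >= 2))
    n_disc = int(round(config.discordant_frac * eligible.size))
    disc_idx = rng.choice(eligible, size=n_disc, replace=False) if n_disc else np.array([], int)
    discordant_gene = np.zeros(n, dtype=bool)
    discordant_gene[disc_idx] = True

    rows = []
    tps = tuple(config.timepoints_h)
    profiles = {a.id: np.asarray(a.profile) for a in ARCHETYPES}
    lo, hi = config.baseline_mean_range
    for gi in range(n):
        k = n_ps[gi]
        silenced = np.zeros(k, dtype=bool)
        if discordant_gene[gi]:
            n_silent = int(rng.integers(1, k))  # nonempty proper subset
            silenced[rng.choice(k, size=n_silent, replace=False)] = True
        for j in range(k):
            ps_id = f"{gene_ids[gi]}_ps{j + 1}"
            baseline = rng.uniform(lo, hi)
            # a zero effect size is no induction, whatever the flag draw
            ps_induced = (
                bool(induced_gene[gi]) and not silenced[j] and z_target_gene[gi] > 0
            )
            if ps_induced:
                sd_b = float(config.sd_curve(baseline))
                lfc = z_target_gene[gi] * sd_b * profiles[archetype[gi]]
            else:
                lfc = np.zeros(len(tps))
            rows.append(
                (ps_id, gene_ids[gi], ps_induced, archetype[gi] if ps_induced else 0,
                 baseline, z_target_gene[gi] if ps_induced else 0.0, *lfc)
            )
    probesets = pd.DataFrame(
        rows,
        columns=["probe_set_id", "gene_id", "induced", "archetype",
                 "baseline_mean", "z_target", *[f"lfc_{t}h" for t in tps]],
    ).set_index("probe_set_id")
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_probe_sets": n_ps,
            "induced": induced_gene,
            "archetype": archetype,
            "discordant": discordant_gene,
        }
    ).set_index("gene_id")
    return TruthTable(probesets=probesets, genes=genes, timepoints_h=tps)


def _sample_ids(config: SimConfig) -> tuple[list[str], list[int]]:
    ids = [f"ctrl_{i + 1}" for i in range(config.n_controls)]
    labels = [0] * config.n_controls
    for t in config.timepoints_h:
        for r in range(config.replicates_per_timepoint):
            ids.append(f"t{t:02d}h_r{r + 1}")
            labels.append(int(t))
    return ids, labels


def simulate_from_truth(
    truth: TruthTable, config: SimConfig, seed: int
) -> SimulatedDataset:
    """Realise a dataset from an existing truth table with fresh noise.

    Used to emulate an independent replication of the same biology (shared
    effect sizes, independent arrays), e.g. a second mouse strain.
    """
    rng = np.random.default_rng(seed)
    sample_ids, labels = _sample_ids(config)
    design = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"),
                       name="timepoint_h")
    baseline = truth.probesets["baseline_mean"].to_numpy()
    lfc = truth.probesets[truth.lfc_columns()].to_numpy()
    tp_index = {t: i for i, t in enumerate(truth.timepoints_h)}
    n_ps = baseline.size
    sd = np.asarray(config.sd_curve(baseline))

    mean_mat = np.empty((n_ps, len(sample_ids)))
    for ci, t in enumerate(labels):
        mean_mat[:, ci] = baseline if t == 0 else baseline + lfc[:, tp_index[t]]
    values = mean_mat + rng.normal(0.0, sd[:, None], size=mean_mat.shape)
    expr = pd.DataFrame(values, index=truth.probesets.index.copy(), columns=sample_ids)

    p_present = 1.0 / (1.0 + np.exp(-(values - config.presence_midpoint)
                                    / config.presence_scale))
    presence = pd.DataFrame(
        (rng.random(values.shape) < p_present).astype(int),
        index=expr.index, columns=sample_ids,
    )
    probe_map = pd.DataFrame(
        {"gene_id": truth.probesets["gene_id"],
         "tag": [pid.rsplit("_", 1)[-1] for pid in truth.probesets.index]},
    )
    probe_map.index.name = "probe_set_id"
    return SimulatedDataset(expr, design, presence, probe_map, truth)


def simulate_timecourse(config: SimConfig) -> SimulatedDataset:
    """Simulate the full replicated time course plus ground truth.

    Induced probe sets receive archetype-shaped mean shifts scaled so that
    the peak log2 fold change equals ``z_target * sd_curve(baseline)``;
    per-array noise is Gaussian on the log2 scale with SD from the same
    curve; presence flags are drawn per cell from a logistic model in the
    noisy expression value.  Identical configs (including seed) reproduce
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _make_truth(config, rng)
    # noise seed derived from the same stream keeps one-seed determinism
    noise_seed = int(rng.integers(0, 2**31 - 1))
    return simulate_from_truth(truth, config, noise_seed)


def simulate_null(config: SimConfig) -> SimulatedDataset:
    """Simulate with no induced genes (all 18 columns exchangeable)."""
    return simulate_timecourse(dataclasses.replace(config, frac_induced=0.0))


# ---------------------------------------------------------------------------
# synthetic 3'-UTR sequences with planted regulatory elements


@dataclass
class SyntheticUtrSet:
    """Synthetic UTR sequences plus the motif occurrences planted in them."""

    records: list[tuple[str, str]]            # (sequence_id, RNA sequence)
    truth: list[MotifHit]                     # planted occurrences, verified

    def truth_for(self, sequence_id: str) -> list[MotifHit]:
        return [h for h in self.truth if h.sequence_id == sequence_id]


_SPACER_ALPHABET = ("C", "G")


def _spacer(rng: np.random.Generator, length: int) -> str:
    # C at both ends blocks junction artefacts with G-containing motifs
    if length <= 2:
        return "C" * max(length, 1)
    inner = "".join(rng.choice(_SPACER_ALPHABET, size=length - 2))
    return "C" + inner + "C"


def generate_utr_set(
    n_seqs: int,
    motifs_per_class: dict[str, int],
    seed: int,
    motif_defs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    max_retries: int = 100,
) -> SyntheticUtrSet:
    """Build sequences containing exactly the requested motif occurrences.

    Each sequence interleaves the planted motif instances (shuffled order)
    with C/G spacers that cannot themselves contain any motif; the assembled
    sequence is re-scanned and rejected if the scan finds anything beyond
    the planted truth (junction artefacts), with bounded retries.
    """
    defs = {d.class_name: d for d in motif_defs}
    for cls, cnt in motifs_per_class.items():
        if cls not in defs:
            raise KeyError(f"unknown motif class {cls!r}")
        if cnt < 0:
            raise ValueError(f"negative count for motif class {cls!r}")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth: list[MotifHit] = []
    for si in range(n_seqs):
        seq_id = f"utr{si + 1:03d}"
        planted_texts = []
        for cls, cnt in sorted(motifs_per_class.items()):
            for _ in range(cnt):
                pattern = str(rng.choice(defs[cls].patterns))
                planted_texts.append((cls, pattern))
        for attempt in range(max_retries):
            order = rng.permutation(len(planted_texts))
            parts = [_spacer(rng, int(rng.integers(6, 21)))]
            planned: list[MotifHit] = []
            pos = len(parts[0])
            for oi in order:
                cls, text = planted_texts[oi]
                planned.append(MotifHit(seq_id, cls, pos, pos + len(text), text))
                parts.append(text)
                pos += len(text)
                spacer = _spacer(rng, int(rng.integers(6, 21)))
                parts.append(spacer)
                pos += len(spacer)
            seq = "".join(parts)
            found = scan_sequence(seq, motif_defs, sequence_id=seq_id)
            if set(found) == set(planned):
                records.append((seq_id, seq))
                truth.extend(sorted(planned, key=lambda h: (h.start, h.class_name)))
                break
        else:
            raise RuntimeError(
                f"could not assemble {seq_id} without accidental motifs "
                f"after {max_retries} attempts"
            )
    return SyntheticUtrSet(records=records, truth=truth)
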