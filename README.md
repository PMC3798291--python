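# actikin — activity-dependent transcriptome kinetics

`actikin` re-implements, as a tested and reusable pipeline, a classic
analysis of the activity-regulated neuronal transcriptome: detecting
stimulus-induced transcripts on replicated expression-array time courses,
clustering their induction kinetics, and mining probe-set-level and
3′-UTR-level signals of alternative transcript usage.  It is aimed at
people analysing small replicated microarray (or microarray-like) time
courses — and at people who want a fully synthetic, ground-truthed test bed
for this style of analysis.

The experimental design it targets: hippocampal RNA profiled on expression
arrays at 0 h (6 control animals) and 1, 4, 8 and 24 h after synchronous
neuronal activity (3 animals each), log2-scale probe-set expression (RMA)
plus binary MAS5-style "present" calls.

## The statistics at its core

**Error model and Z value.**  The SD of biological replicates is strongly
expression-dependent, so per-probe-set control SDs are smoothed against
the control mean with loess (span 0.75, locally quadratic), giving a curve
σ(μ).  The induction statistic for probe set *g* at timepoint *t* is

    Z(g,t) = ( x̄ₜ(g) − x̄₀(g) ) / σ( x̄₀(g) )

and *g* is called **induced** when Z > 5 at any timepoint and the probe
set is present on ≥ 3 arrays.

**Permutation FDR.**  The false discovery rate of that compound rule is
estimated by 25 random 3-vs-3 splits of the 6 control arrays: each split
is treated as a fake timepoint (error model refitted on the remaining
pseudo-controls), and FDR = mean null positives / observed positives.

**Kinetic clustering.**  Induced probe sets' log ratios at 1/4/8/24 h are
normalised to unit Euclidean norm and partitioned by k-means (k = 5, 25
restarts).  Labels are canonical: 1 fast-sustained, 2 fast-transient,
3 late-peaking (8 h), 4 biphasic (1 h + 24 h), 5 slow-rising (24 h).

**Probe-set discordance.**  A gene with at least one induced and one
assessable-but-flat probe set (e.g. 4 induced of 6) is a candidate
activity-dependent exon switch or alternative 3′-UTR user; probe sets
absent from almost all arrays are "unassessable" and never count as
evidence of non-induction.

**3′-UTR motif scanning.**  Exact-match scanning for AU-rich elements
(AUUUA), U-rich motifs (UUUAAA), K-boxes (UGUGAU), UUGUUGG(G) elements and
polyadenylation signals (AAUAAA/AUUAAA); every distinct start position
counts, overlaps allowed, greedy UUGUUGG(G) counted once per start.

A seeded synthetic-data generator (`actikin.simulate`) produces the full
design — heteroscedastic log2 noise, five kinetic archetypes, multi-probe-set
genes with planted discordance, presence flags, and UTR sequences with
planted motifs — together with ground-truth tables for recovery scoring.

## Worked example

The `analysis/` scripts run the whole study on synthetic data (seed 1) and
narrate what they find; `results/` receives all tables.

```bash
python analysis/01_simulate_timecourse.py 1
python analysis/02_fit_error_model.py
python analysis/03_detect_induced.py 1
python analysis/04_cluster_kinetics.py 1
python analysis/05_splice_discordance.py
python analysis/06_scan_utr_motifs.py 1
```

Output of steps 03–05 (abridged):

```
induced probe sets: 623 / 3417 (400 genes)
sensitivity vs truth: 1.000; truth-based FDR: 0.0000
permutation FDR estimate: 0.0000 (mean null positives 0.00 over 25 permutations)

cluster sizes: 1: 100, 2: 131, 3: 137, 4: 132, 5: 123
adjusted Rand index vs generating archetypes: 1.000

discordant                 7
planted discordant genes recovered: 100.00% (7/7); false flags: 0
```

Reading: all 623 planted induced probe sets (400 genes) are recovered with
no false calls; the permutation estimate confirms the FDR is far below the
0.05 design bound; the five kinetic clusters match the generating
archetypes perfectly (ARI 1.0); and all 7 genes with a planted silent
probe-set subset — the exon-switch signature — are flagged with no false
flags.

The same stages are available as a CLI (`actikin simulate|fit-error-model|
detect|fdr|cluster|splice|scan-motifs|run-full`) operating on TSV/JSON
files, and as plain library functions.  Result tables are tab-delimited
with a header row; the calls table columns are `probe_set_id, gene_id,
Z_1h, Z_4h, Z_8h, Z_24h, max_z, peak_timepoint, present_count, induced`.

## Layout

- `src/actikin/` — the library: `simulate`, `io`, `error_model`,
  `detection`, `clustering`, `discordance`, `motifs`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property and end-to-end recovery tests)
- `docs/methods.md` — model, assumptions, parameter choices, limitations
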