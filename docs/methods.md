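# Methods

## Design and model

The pipeline analyses a replicated stimulation time course measured on
expression arrays: `n₀` control arrays at 0 h (default 6) and `r`
biological replicates at each post-stimulus timepoint (default 3 at 1, 4,
8 and 24 h), as log2-scale probe-set × sample expression (RMA-style
summaries are the expected input; the package never touches probe-level
data) plus a binary presence matrix standing in for MAS5 "present" calls.

### Error model

Replicate noise on the log2 scale is strongly mean-dependent.  For every
probe set the mean and sample SD (ddof = 1) over the control arrays are
computed, and SD is smoothed against mean by loess with span 0.75 and
local degree 2 — the defaults of the canonical loess implementation, which
is what "standard parameters" is taken to mean.  The smoother is
implemented in-package as tricube-weighted local quadratic regression and
agrees with R's `stats::loess(..., surface = "direct")` to ~1e-6 on smooth
data (verified in the test suite by calling Rscript).  The fit is
tabulated on a 128-point grid over the observed mean range; evaluation is
linear interpolation inside the support and **constant extrapolation**
outside it, with predictions floored at 1e-6 — both choices prevent
negative or exploding SD predictions at the edges.  No correction is
applied for the small-sample bias of the SD estimator (E[s] ≈ 0.95 σ at
n = 6); the resulting slight Z inflation is shared by the permutation
null, so the FDR estimate remains internally consistent.

### Z statistic

Z(g,t) = (mean_t − mean_0h) / σ(mean_0h).  Three open choices and how they
were fixed:

- **Where to evaluate σ** (control mean, timepoint mean, grand mean): the
  control mean, because the curve is estimated from control replicates and
  the control mean is the only quantity shared by all timepoint contrasts.
- **Replicate-count scaling**: none by default.  The statistic divides a
  difference of means (SD √(1/r + 1/n₀) ≈ 0.71 σ for the default design)
  by a per-array σ, making it conservative; an optional
  `scale_by_replicates` flag rescales by √(1/r + 1/n₀) for users who want
  a mean-difference calibration.
- **Sidedness**: induction-only (Z > 5) by default; a two-sided flag uses
  |Z| and captures downregulated transcripts.

### Detection and permutation FDR

Induced = Z > 5 at any timepoint AND present on ≥ 3 arrays (both
configurable; a stricter presence rule of "half or more samples" is a
defensible alternative and is reachable through `min_present_arrays`).
The FDR of the compound rule is estimated by treating random subsets of
the control arrays as a fake timepoint.  With 6 controls and 3-array
pseudo-timepoints there are only C(6,3) = 20 distinct splits, so the
default 25 permutations draw all 20 distinct splits first and the
remainder with replacement.  Each permutation refits the error model on
its 3 pseudo-controls, so the null mimics the full procedure, not just the
thresholding.  FDR = mean null positive count / observed positive count;
an observed count of zero reports FDR 0 with a warning.

### Kinetic clustering

Induced probe sets' log ratios at the post-stimulus timepoints are
normalised to unit Euclidean norm (the 0 h ratio is identically zero and
is excluded — it carries no shape information but shrinks all distances).
Sign is preserved so downregulated shapes stay representable.  k-means
(Euclidean, k = 5, 25 random restarts, best inertia kept, seeded) clusters
the unit profiles; scikit-learn's implementation is used, which re-seeds
empty clusters internally.  Labels are canonicalised by sorting centroids
by (peak timepoint ascending, off-peak mean descending): among clusters
peaking together at 1 h the sustained shape precedes the transient one,
and the biphasic shape (high 1 h shoulder) precedes the slow riser among
24 h peaks.  This reproduces the conventional early-to-late cluster
semantics (1 fast-sustained … 5 slow-rising).  k = 5 is the default
because the design's four timepoints support about five distinguishable
kinetic shapes; k is configurable.

### Discordance

Gene-level tallies over induction calls: probe sets present on fewer than
`min_assessable_present` arrays (default: the detection presence
threshold) are "unassessable" and excluded from the induced/uninduced
dichotomy, because a never-expressed variant's probe set is not evidence
of non-induction.  A gene is discordant iff it retains ≥ 1 induced and
≥ 1 non-induced assessable probe set; the same Z > 5 rule is reused at
probe-set level, there being no separate probe-set criterion.  Candidates
are ranked by max induced Z; an optional kinetic filter marks genes whose
induced probe sets land in different clusters.  The module works at
probe-set granularity only — which exon or UTR a probe set covers must
come from the mapping file's tag column.

### Motif scanning

Exact string matching on U-normalised, upper-cased sequence (T ≡ U; N
matches nothing; illegal characters are an error with position).  Classes
and default patterns: ARE `AUUUA`; URM `UUUAAA`; K-box `UGUGAU` (the core
hexamer of the cUGUGAUa consensus — K-box consensus usage varies across
tools, so this class is configurable); UUGUUGG with an optional trailing G
matched greedily and counted once per start; polyadenylation signals
`AAUAAA` and `AUUAAA`.  Every distinct start yields a hit and overlaps are
allowed within and across classes — this **overlap policy changes counts**
in AU-rich stretches (AUUUAUUUA = 2 AREs) and is therefore stated
prominently.  Sequences are scanned as given (sense strand only).

## Synthetic data

The generator emulates the study design: baseline means uniform on
[4, 14] log2 units (the typical RMA range, chosen to exercise the whole
mean–SD curve); per-array Gaussian noise on the log2 scale with SD from a
monotone-decreasing curve σ(μ) = a + b·e^(−cμ) (defaults a = 0.1, b = 1.5,
c = 0.35, giving ~0.5 log2 units of noise at the bottom of the range and
~0.1 at the top); Gaussian noise matches the Z statistic's implicit
assumption.  20% of genes are induced; each induced gene draws one of five
kinetic archetypes (fast-sustained, fast-transient, late-peak 8 h,
biphasic 1 h + 24 h, slow-rising 24 h, equal weights) and a target peak Z
uniform on [8, 15]; its planted log2 fold change at timepoint *t* is
`z_target · σ(baseline) · archetype_profile(t)`.  20% of genes carry 2–7
probe sets; 10% of induced multi-probe-set genes are "discordant": a
random nonempty proper subset of their probe sets receives zero induction
(the 4-of-6 pattern).  Presence flags are logistic in the noisy expression
value (midpoint 2.5, scale 0.5 log2 units), giving ~95% presence at the
lowest baseline — the presence filter is non-vacuous but rarely decisive.
All draws flow from one `numpy` Generator per config seed, so identical
configs reproduce byte-identical outputs.

The UTR generator interleaves requested motif instances (shuffled order)
with C/G spacers that begin and end with C, then re-scans the assembled
sequence and rejects it if anything beyond the planted truth is found
(bounded retries); the delivered truth is therefore verified, not assumed.

What the generator does **not** emulate: probe-level effects and
summarisation artefacts, spatial array artefacts, correlated noise between
probe sets of one gene, outlier arrays, non-Gaussian heavy tails, and
inter-animal biological variability beyond the replicate SD.  Recovery
tests on this data therefore demonstrate the correctness and calibration
of the procedure under its own assumptions, not its robustness to real
microarray pathology.

## Numerical and testing choices

- Loess evaluation on a 128-point grid + linear interpolation keeps model
  fitting O(grid × n) instead of O(n²); the grid is dense enough that the
  interpolation error is far below the replicate-SD noise floor.
- Degenerate inputs: a single-mean dataset yields a constant error model;
  zero-norm profiles are dropped (all-zero input is an error); singleton
  clusters get zero-width bands; zero observed positives give FDR 0 with
  a warning.
- Determinism: every stochastic step (simulation, permutation splits,
  k-means restarts) takes an explicit seed; the pipeline fans one global
  seed out to per-stage seeds recorded in the run manifest.
- Test problem sizes: recovery and calibration tests use 400–5000 probe
  sets and 10–20 replicate simulations — large enough that the binomial
  Monte-Carlo error on the quantities under test is a few percent, small
  enough to keep the suite fast.  The null-calibration check compares the
  truth-based false-positive rate with the permutation estimate within a
  factor of 2, with both rates below one expected count treated as
  agreement (at Z > 5 the null tail mass is orders of magnitude below one
  call per 5000 probe sets, so both sides of the comparison are almost
  always exactly zero).

## Known limitations

- The error model assumes exchangeable control replicates and Gaussian
  log-scale noise; heavy-tailed noise would inflate the FDR relative to
  the permutation estimate.
- With 6 controls the permutation null has only 20 distinct splits, so
  the FDR estimate's resolution is limited; it is a bound-style check,
  not a precise rate.
- The mean–SD default curve is a plausible parametric stand-in, not a fit
  to any particular array dataset; users analysing real data should let
  the error model be fitted on their own controls (it always is) and
  treat the generator's curve only as a test-bed setting.
- Discordance inherits all detection errors; near-threshold effects
  produce unstable statuses, which is why recovery is only claimed at
  peak Z ≥ 8.
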