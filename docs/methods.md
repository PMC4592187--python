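# Methods

This note documents the statistical model behind `synerseq`, the simulator
used to validate it, the numerical conventions, and the design choices made
where the problem was genuinely open.

## The factorial design and its contrasts

The package targets a two-stressor factorial layout: stressor A applied at a
series of doses (0 = vehicle), stressor B as an on/off factor, several time
points, and a fixed number of biological replicates per condition cell. Four
condition *roles* are resolved per time point — vehicle (dose 0, B off),
A-alone (top dose, B off), B-alone (dose 0, B on) and the combination (top
dose, B on) — and every question the pipeline asks is a pairwise contrast
between two cells:

* combo vs vehicle, A vs vehicle, B vs vehicle → global synergy counts;
* combo vs A-alone **and** combo vs B-alone → SA-DEGs;
* combo-at-each-dose vs B-alone, plus combo vs vehicle → the dose filter.

## Differential expression model

Expression is normalized to RPKM (`count / (length_kb × library_size/10⁶)`);
library sizes default to within-matrix column sums, which makes the
conservation identity `Σ_g rpkm[g,s]·length_kb[g] = 10⁶` exact per sample and
is the closest reading of "per million reads sequenced" available from a
count matrix alone. The testing scale is log₂(RPKM + pseudocount), pseudocount
1.0 by default: the log transform stabilizes the multiplicative NB variance,
while the fold-change gate is evaluated on untransformed linear replicate
means so that the ±2 threshold keeps its literal meaning.

The per-gene test is a one-way fixed-effects ANOVA. Two formulations are
provided:

* **Two-group** (`anova_gene`, and `call_degs` default): F on
  (k−1, N−k) degrees of freedom using only the contrast's own groups. For
  two groups this equals the squared pooled-variance t statistic (F = t²),
  which the tests assert.
* **Protected contrast with pooled error** (`call_degs` with
  `error_conditions`, used by the pipeline): the within-group mean square is
  pooled across every condition cell of the same time point, and the
  contrast's mean difference is referred to a t distribution on the pooled
  degrees of freedom. This is the classical multi-group ANOVA treatment of
  pairwise comparisons. With three replicates the two-group error term has
  only 4 df, so even a true 4-fold change yields p ≈ 10⁻³ — too weak to
  clear a BH family of several thousand genes; pooling across the eight
  cells of a time point raises the error df to ~16 and restores the power a
  per-gene ANOVA needs at this replication level. With `error_conditions`
  equal to the contrast's two conditions the pooled formula reduces exactly
  to the two-group ANOVA, so the default behavior is unchanged.

Degenerate conventions: all values identical → F = 0, p = 1; zero
within-group variance with differing means → p = 0 with a degenerate flag;
fewer than two non-missing replicates on either side → `untestable`, and
untestable genes are excluded from the BH family. The BH family is all
testable genes of one contrast at one time point, matching the fact that
every reported DEG count is attached to one specific comparison.

Fold changes use the signed-ratio convention (+test/ref or −ref/test, so
|fc| ≥ 1 always). A zero reference mean with a positive test mean gives +∞
(which passes the magnitude gate deterministically); both means zero is
untestable. Thresholds are inclusive: |fc| ≥ 2, q ≤ 0.05.

## The synergy cascade

* **SA-DEGs**: DE (up or down) in combo-vs-A *and* combo-vs-B. Genes whose
  direction disagrees between the two contrasts are retained but flagged
  `discordant` — the definition does not address the case, and flagging
  preserves information that dropping would destroy.
* **Global synergy**: `n_combo > n_A + n_B`, strict. The comparison is
  symmetric in the two single treatments.
* **Unique genes**: DE in combo-vs-control but in neither single-stress
  contrast vs control; the fraction of unique genes among SA-DEGs measures
  how much of the combined response is invisible in either single profile.
* **Monotone dose filter**: fold changes are mapped to a signed-log₂ axis
  (±r → ±log₂ r), removing the signed-ratio discontinuity at ±1 so that
  non-strict monotonicity (ties allowed, either direction) is well defined.
  A series that crosses sign fails: "dose-responsive" means moving away from
  baseline consistently. The top-dose condition must additionally be a DEG
  against the non-treated vehicle control.
* **Persistence**: sustained genes must be members of the *late SA-DEG set*
  (same double-contrast definition at the late time point), not merely DE vs
  control late — the stricter reading of "still synergistically altered".

The composition invariant `sustained ⊆ signature ⊆ SA-DEG(early)` (and
`signature ⊆ dose-responsive`) is asserted on every pipeline run.

## Enrichment and the pathway graph

Over-representation is the MSigDB-style hypergeometric upper tail
P(X ≥ k) with population = universe, successes = set ∩ universe, draws =
query; q-values are BH across the collection. The default universe is the
union of all genes in the GMT collection — the original platform's gene
list is not recoverable, and an explicit universe (e.g. all expressed
genes) can be supplied instead. k/K ratios are formatted to 4 decimals and
candidate percentages to 1 decimal, matching the conventions of the
published tables they are checked against.

The pathway-overlap network connects two significantly enriched sets
(q ≤ 0.05 by default) when their shared genes reach 10% (inclusive) of the
*smaller* set and at least one query/signature gene is shared. The source
description says only "10% overlap of genes"; min-denominator is the
inclusive choice, and union (Jaccard) or mean denominators are available as
options.

## The simulator

`simulate_experiment` draws counts from a negative binomial with
Var = μ + α·μ² (α = `dispersion`, the reciprocal of the NB size parameter;
α = 0 selects Poisson). The per-gene mean is log-linear:

    log₂ μ = baseline + a·f(dose) + b·[B on] + c·f(dose)·[B on]·persist(t)

with f(dose) = dose / max(dose) — the simplest monotone link, since only a
monotone trend is asserted downstream. Gene classes: null (a=b=c=0), A-only,
B-only, additive (a, b ≠ 0, c = 0) and synergistic. Synergistic genes are
planted as *pure interactions* (a = b = 0, c = ±`interaction_log2fc`): this
makes the truth table unambiguous for SA-DEG recovery and reproduces the
study's observation that most SA-DEGs are "unique" — invisible in either
single-stressor profile. `persist(t)` is 1 except at the final time point of
a multi-time-point design, where it is 0 unless the gene was planted
persistent; main effects do not decay. Whole-sample dropout
(`missing_replicate_rate`) removes at most one replicate per condition cell
(never below two), mirroring a lost library rather than gene-level
missingness — gene-level zeros arise naturally from NB sampling.

Defaults: 3 replicates; times 4/8/24 h; doses 0/0.2/0.5/1.0 (fully crossed
with the B flag; `time_course_config` and `dose_response_config` give the
two sub-designs of the emulated study, 36 and 24 samples respectively);
baseline log₂ expected counts uniform on (4, 11), anchored to the emulated
study's sequencing depth (~20 M reads/sample, ~40% retained, spread over
the coding gene set gives a median of a few hundred counts per gene);
dispersion α = 0.05 (a typical cell-line biological-replicate value);
library-size factors uniform within ±20%; effect and interaction magnitudes
2.0 on the log₂ scale with random sign.

**What the simulator does not emulate:** batch effects, gene–gene
correlation, length-dependent count bias, multi-mapping artifacts, or the
specific biology of the PKC/p53 pathways. Passing recovery tests therefore
demonstrates the correctness of the filtering logic under the stated noise
model, not performance on any real dataset.

**A known identifiability limit of the method itself:** an additive gene
whose two main effects both exceed the fold-change threshold is
indistinguishable from a synergistic gene under the double-contrast SA-DEG
definition (combo-vs-A detects b, combo-vs-B detects a). Truth-recovery
metrics are therefore evaluated on simulations that plant pure-interaction
genes alongside null and single-effect classes; when additive genes are
planted, they contaminate the SA-DEG set by construction and the
module-level tests compare against the method-recoverable truth instead.

## Problem sizes and numerics

Simulation-based checks use 5 000 genes (150 synergistic, 30% persistent)
for calibration and recovery, and a few hundred genes for pipeline
composition tests. Null p-value uniformity is assessed by the
Kolmogorov–Smirnov statistic; FDR control by the realized fraction of null
genes at q ≤ 0.05 against its binomial standard error. Within-group sums of
squares below 10⁻¹² of the total are treated as exactly zero (degenerate
conventions above). All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configurations produce byte-identical
fixture files.

## Known limitations

* The per-gene ANOVA assumes equal within-group variance on the log scale
  across the pooled cells; strong mean–variance coupling at very low counts
  violates this mildly (the pseudocount damps it).
* No shrinkage/moderation of per-gene variances is performed by design — the
  package reproduces a classical ANOVA workflow, not a modern
  empirical-Bayes DE method.
* Gene identifiers are matched exactly; no alias resolution.
* The published q-values of external enrichment databases are not
  reproducible (their universes and collection versions are unpublished);
  only k, K and k/K are re-derived.
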