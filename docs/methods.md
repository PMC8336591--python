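# Methods

## The problem and the estimand

Two cohorts A and B of S_A and S_B subjects each contribute one paired
two-condition transcriptome (e.g. tumor and matched normal from the same
person). For every gene set *gs* the question is whether the *degree of
within-subject responsiveness* of that set differs between the cohorts —
an interaction between the within-subject factor (condition) and the
between-subject factor (cohort) — at sample sizes far below what
transcript-level cohort models need.

The estimand is θ_K, the expected continuity-corrected log odds ratio of
per-subject DEG enrichment in cohort K; the test contrasts θ_A against
θ_B. No per-subject random effect is modeled: the cohort mean's variance
is taken from the within-subject (Woolf) variances alone, exactly as the
statistic is defined. Consequences of this choice are discussed under
Limitations.

## Per-subject stage (MixEnrich)

Within one subject, log2 fold changes are computed from pseudocounted
counts, `log2(case) − log2(baseline)`. The absolute values are modeled as
a two-component mixture:

* **Null component** — half-normal anchored at zero. Measurement noise in
  log-ratio space is symmetric around zero, so its absolute value is
  half-normal. Its scale is estimated by central matching,
  `s0 = median(|log2FC|) / 0.6745` (the half-normal median factor), on the
  empirical-null rationale: the bulk of the transcriptome is unchanged, so
  the distribution's centre identifies the noise scale. The scale is held
  fixed during EM.
* **DE component** — a Gaussian with free weight, mean and sd, the mean
  constrained to at least `2·s0` (a differentially expressed gene must
  shift beyond noise). The constraint is applied by clamping the M-step
  mean update, which is the constrained argmax of the EM surrogate, so the
  log-likelihood remains non-decreasing.

Why the constraints: an unconstrained two-Gaussian fit on |log2FC| is
bistable. On a subject with no differential signal the maximum-likelihood
solution splits the half-normal bulk into two balanced overlapping
components, and the wider one then "owns" the upper tail — 20–30% of
unchanged genes get DE posterior > 0.99, a rate that varies from subject
to subject. Anchoring the null at zero with a robust fixed scale and
keeping the DE mean out of the null body makes the posterior gate specific
(<2% calls on pure half-normal data, measured ≈0%) and, critically, makes
the background call rate *the same in both cohorts*, which the downstream
log-OR contrast needs: with only a few hundred counts per contingency-table
cell, an asymmetric background rate interacts with the +½ continuity
correction and biases the cohort contrast at large S. Because the null is
pinned at zero the fit is equivariant under scaling of the data but not
under translation.

Numerical choices: EM tolerance 1e-8 on the absolute log-likelihood
change, at most 500 iterations, sd floor 1e-3 against component collapse,
deterministic initialization (split at the 90th percentile; median split
as a tie fallback). Degenerate inputs — fewer than 50 values, negative
values, all values identical — are rejected. The fit draws no random
numbers; identical data give identical fits.

DEG gates are strict inequalities: posterior > 0.99, and in real-data mode
additionally |log2FC| > log2(1.2). Simulation mode uses the posterior gate
alone. An externally produced boolean DEG vector can be substituted for
the mixture stage (`DegCall.from_boolean`), so any single-subject caller
can feed the enrichment machinery. We fit on raw |log2FC| without
standardization; a per-gene standardization would require a noise model
per expression stratum and, in our measurements, does not move the
detection boundary (see Limitations).

## Per-subject enrichment

For each (subject, gene set) the 2×2 table cross-classifies DEG status
with membership over the filtered analysis universe; gene sets are
intersected with the universe first. Two statistics are computed:

* two-sided Fisher exact test on the raw integer counts (sum of
  hypergeometric probabilities no larger than the observed table's), with
  BH adjustment across the collection and an `enriched` flag at FDR 5%;
* the continuity-corrected natural-log odds ratio Q and its Woolf variance
  with +½ in every cell. The correction keeps both finite for any table —
  every subject contributes a usable effect size, which is the point of
  the method. It applies only to Q/var(Q), never to the Fisher test.

## Cross-cohort test

Per set: cohort means Q̄_K with variance ΣvarQ/S_K²; the contrast
W = (Q̄_A − Q̄_B)/√(var Q̄_A + var Q̄_B); two-sided normal p-values; BH
across all N sets passed in (never hard-coded: 4 in the simulation design,
thousands in a genome-wide screen). After BH, the negative-means rule sets
adjusted p to 1.0 where both cohort means are negative — a set
impoverished of DEGs in both cohorts is not biologically interpretable as
a discovery. Suppression operates on adjusted values (the other q-values
are not recomputed), uses strict `< 0` on both means, and can only remove
significance, never create it. Cohorts must not share subjects.

## GLM+EGS comparator

The conventional baseline, as a documented simplification of the
limma-voom workflow it stands for: TMM normalization (M-trim 30%, A-trim
5%, precision-weighted, factors geometric-mean-normalized to 1), log-CPM
with prior count 0.5 on TMM-effective library sizes, reduction of each
subject to its within-pair log-ratio — which captures subject blocking in
a paired design exactly — and a moderated two-sample t between cohorts:
per-gene variances shrunk toward a scaled-F prior fit by method of moments
on log s² (trigamma inversion by Newton iteration; prior df may be
infinite when no excess spread exists), t referred to df_residual +
df_prior. No per-sample quality weights are estimated; that is the main
fidelity gap versus the original pipeline. DEGs at q < 0.05 (strict; plus
a fold-change gate in real-data mode) feed a Fisher enrichment over the
collection with BH across sets. An empty DEG list yields no enriched sets,
not an error. A `simple` contrast (case samples only, no pairing) is also
provided.

## Preprocessing

Two regimes, both explicit about their threshold semantics:

* **Single-subject (union) filter** — per pair, genes with within-pair
  mean ≤ `min_mean` are dropped (strict `<` in simulation mode); the final
  list is the union over pairs of survivors; the pseudocount (default 1)
  is added to every retained count. Real-data default `min_mean = 5`,
  simulation default 30.
* **CV filter (GLM real-data mode)** — transcripts with a zero count in
  any sample are removed first (the conservative reading that guarantees
  CV and log transforms are defined), the rest ranked by sd/mean, the top
  `ceil(fraction·n)` kept (ceil so a nonzero fraction always keeps ≥1
  gene; stable sort on ties).

## Simulator

Emulates a two-cohort paired tumor–normal benchmark with known truth. All
randomness flows from one seed; datasets are bit-reproducible.

| parameter | default | meaning |
|---|---|---|
| n_genes | 17 414 | filtered transcriptome size |
| cohort_size | 3 | subjects per cohort (grid: 2, 3, 7, 10, 30) |
| prop_coordinated | 0.48 | P(subject shares the common DEG selection) (grid: 0.25, 0.48, 0.75) |
| gamma_shape, gamma_scale | 0.55, 6.06 | seeded-DEG log2FC distribution (mean ≈ 3.3) |
| enriched_sets | (200, 0.10), (40, 0.10) | (size, DEG proportion); DEG count = round-half-up |
| control_sets | 196, 41 | sizes of unseeded sets |
| baseline_mean_log, baseline_sd_log | ln 200, 1.5 | log-normal gene means (counts scale) |
| dispersion: intercept, slope, sd_log | 0.01, 1.0, 0.5 | NB dispersion trend a + b/mean with log-normal gene-wise spread |
| n_replicate_pairs | 7 | same-condition pairs feeding the null-FC pool |

Construction: gene means are log-normal; counts are negative-binomial
(gamma–Poisson) with gene-wise dispersion drawn around an
isogenic-replicate trend (BCV ≈ 0.1 at high expression — replicate noise
of a cell-line experiment, not the much larger between-patient
heterogeneity; the log-normal spread gives the genuine gene-to-gene
variance heterogeneity that moderated-t priors rely on). Seven replicate
pairs of such baselines yield an empirical pool of null log2FCs
(pseudocount 1), binned by deciles of baseline expression; bins containing
zero baseline expression are merged into one low-expression category. A
non-DEG tumor count is `round(normal · 2^L)` with L drawn from the bin
holding that gene's baseline expression; a DEG tumor count uses a positive
Gamma(0.55, 6.06) draw instead. Gene-set memberships (2 enriched + 2
control, disjoint) are redrawn per dataset; per enriched set one shared
DEG selection is drawn, each cohort-A subject is coordinated with
probability `prop_coordinated` (coordinated subjects reuse the shared
selection, others draw their own of the same size), and cohort B receives
no seeded DEGs. The grid schedule derives per-dataset seeds from the base
seed through `SeedSequence` spawn keys, so a base seed determines every
dataset. A user-supplied real baseline matrix and replicate pairing can
replace the synthetic generator for fidelity runs.

What the generator does **not** emulate: between-subject biological
heterogeneity of baselines (each subject is a fresh draw from one
population), library-size variation and batch effects, negative (downward)
DEG fold changes, correlated co-expression structure within gene sets, and
the GO DAG (sets are random memberships). Passing benchmarks therefore
demonstrate the statistical machinery under the stated noise model, not
performance on any particular clinical dataset.

## Accuracy measurement

Confusion counts over an explicit set universe; precision/recall in
traditional or small-sample-adjusted form ((tp+0.5)/(tp+fp+1), same for
recall), with the zero rule first in both modes: a method with no positive
predictions scores (0, 0). Simulation scoring uses the traditional
formulas; real-data scoring against an empirical reference uses the
adjusted ones; the mode is always explicit. A similarity-matched variant
accepts a symmetric pairwise similarity matrix between set identifiers and
counts matches at similarity ≥ 0.70 (identical identifiers always match);
with the identity matrix it reduces to exact matching. Benchmark summaries
report both per-replicate medians/quartiles and pooled-confusion
precision/recall per configuration; a method failure on a dataset is
logged and scored as no-positives.

## Reference study and problem sizes

`internof1.study.run_reference_study` runs the 5×3 grid at 17 414 genes
with 30 replicate datasets per configuration and 10 at 30vs30 (the
largest size dominates runtime; ~5 min total on one CPU). Headline
summaries: worst-configuration median per-replicate precision and recall
at 3vs3; the minimum pooled per-configuration precision over the grid; and
the GLM+EGS comparator's largest median per-replicate accuracy at 2vs2
(medians because the zero rule makes them the faithful summary of a
method that typically returns no positives, where pooling a handful of
lucky replicates would degenerate).

Measured behavior (seeds 1 and 7): median precision 1.0 in every
configuration; pooled precision ≥ 0.95 everywhere; GLM+EGS medians 0/0 at
2vs2 (it finds a true set in roughly 1-in-6 replicates under high
coordination — its pooled recall at 2vs2 is 0.07–0.25 — and becomes
competitive only at 30vs30 with high coordination); Inter-N-of-1 recall
rises from ≈0.5 (median) at 2–3 subjects to 1.0 at 30.

## Known limitations

* **Small-set detection floor.** A set with only ~4 seeded DEGs cannot be
  reliably detected at 3vs3: the unenriched cohort's empty in-set cell
  contributes 1/(0+½) = 2 to var(Q) per subject, capping
  W ≤ √3·ln(2g_A+1)/√(2 + 1/(g_A+½)) ≈ 2.0–2.55 even at perfect
  sensitivity, and about half the Gamma(0.55, 6.06) fold-change mass lies
  below any feasible detection threshold. Raising the background call rate
  does not help — it shrinks the cohort contrast faster than the variance.
  Per-replicate recall at 3vs3 is therefore typically 0.5 (the 200-gene
  set is found, the 40-gene set ~30% of the time), rising with cohort
  size. This is a property of the statistic under the stated simulation
  parameters, not of the implementation.
* **No between-subject variance component.** Ignoring extra-Woolf
  variation in Q makes W slightly anti-conservative as S grows; at 30vs30
  the detected true DEGs of the enriched cohort also inflate the h cell of
  control-set tables (a bias of order n_DEG/(n_genes · background rate)),
  which is negligible at genome scale but grows if the universe is
  aggressively reduced.
* **Comparator fidelity.** The moderated paired t without voom quality
  weights retains marginal power at 2vs2 for extreme coordinated effects;
  conclusions about the comparator at that size are about its typical
  (median) behavior.
* **Transcript independence** is assumed by both the Fisher test and the
  BH adjustment, as in the method being implemented.
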