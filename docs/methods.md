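# Methods

This note documents the statistical procedures implemented in
`toxcascade`, the assumptions behind them, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Data model and assumptions

A *time series* is one (compound, dose level) trajectory over an ordered
set of measurement times (hours post first dose). Dose levels are ordinal
labels and are never compared numerically — dose concordance is out of
scope. Each treated (compound, time) condition must have a matched vehicle
control at the same compound and time; expression is assumed
log2-normalised upstream (array preprocessing and QC are not
reimplemented). Gene identity is case-sensitive symbol matching with no
ortholog translation. The minimum number of measured timepoints for a
series to enter the analysis is 6 (configurable).

An *event* is a directional change of an entity at one of four levels:
`gene`, `pathway` (gene-set activity), `tf_activity` (regulon activity) and
`tf_expression` (the TF's own transcript). Up and down are independent
events; a single entity can first-activate in both directions within one
series, and no mutual exclusion is enforced.

## Activity scoring

`activity.score_gene_sets` implements the GSVA-style single-sample
statistic: for each gene, a Gaussian-kernel estimate of the cumulative
density of its expression across the sample universe (bandwidth = per-gene
SD / 4; degenerate zero-variance genes get a near-delta kernel); per
sample, genes are ranked by this value (stable tie-break by row order) and
weighted by |p/2 − rank|^τ with τ = 1; each set is summarised by a
weighted Kolmogorov–Smirnov-like random walk down the ranking. The walk is
evaluated only at member-gene positions (it rises only there and decays
linearly between), which makes scoring O(m log m) per set and sample.

Two ES forms are available: `max_dev` (default) — the signed maximum
deviation of the walk — and `diff` — the sum of the maximum positive and
minimum negative deviations. Both are bounded in [−1, 1]. A `zscore`
fallback (combined z of per-gene standardised values, mapped into (−1, 1)
through the normal CDF) exists so downstream stages can be exercised
without the kernel scorer; it is not the default.

The sample universe matters: scoring is per compound (all doses, timepoints
and vehicle controls of one treatment), mirroring per-treatment
normalisation. `score_per_compound` handles the loop.

Regulons are filtered to confidence grades A–C before scoring, and members
with a negative mode of regulation are removed, so regulon score direction
equals inferred TF-activity direction. All sets require ≥ 5 members present
in the expression universe (configurable `min_set_size`).

## Differential testing

Per compound, a group-means model (one group per dose × time × control
status) pools a per-row residual variance s²_g with df = n − G. Empirical-
Bayes moderation shrinks s²_g toward a prior s₀² with prior df d₀ estimated
from the distribution of log s²_g by the standard scaled-F moment equations
(trigamma inversion by Newton iteration); the moderated t uses
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and a t reference with d + d₀ df (normal
when d₀ is infinite). Setting `prior_df=0` reproduces the ordinary
two-sample t exactly — the limiting case is tested to 1e-10. Contrasts with
fewer than two treated or two control replicates are skipped and logged;
zero residual df for a compound is a hard error.

The "logFC" of a set-level event is the treated-minus-control difference of
mean activity scores. Scores are not log-ratios; the term is kept because
gene- and set-level effects flow through identical downstream machinery and
the field uses the word uniformly.

FDR is Benjamini–Hochberg within each (compound, level) family — the
per-treatment scope matching the per-compound normalisation; the family is
configurable since no single convention is universal.

## Events and first activation

An event first-activates at the earliest timepoint with FDR < `fdr_max`
(default 0.05, strict) and |effect| > `min_abs_effect` (strict; default 0
for set-level events, 1.0 for gene-level, 0.5 for TF expression in the
cascade context). Missing timepoints are skipped, never interpolated; there
is no smoothing or change-point estimation — detection is threshold
crossing on per-timepoint tests, so the first-activation time is always one
of the measured times and is right-biased when power is low at onset.
Tightening either criterion can only delay or remove a first activation
(property-tested).

## Histopathology

Severity grades map to normal = 0, minimal = 1, slight = 2, moderate = 3,
marked/severe = 4 and are averaged over replicates into a toxscore in
[0, 4]; absent entries mean 0. Each finding is binarised at "null"
(toxscore > 0), "low" (> 0.67) and "high" (> 1.34) — strict inequalities,
so a score of exactly 0.67 does not trigger "low", and a score of 1 carries
"null" and "low" but not "high". A label is *adverse* iff it occurs in
≥ `min_adverse_count` (default 5) adverse-annotated series and
≥ `min_adverse_fraction` (default 50%) of all its occurrences are adverse.
The adverse/non-adverse annotation itself is consumed as external expert
input and never derived from expression.

The first adverse time of a series is the earliest occurrence of any
selected label; all labels present at that time form the primary adverse
phenotype. *Background* series have no histological finding of any kind
and, under the default strict rule, belong to compounds not annotated
adverse at any dose; a looser `non_adverse` mode is available.

## Time concordance

For each preceding event PE and the later event LE, evaluable LE-series
split into a (PE before-or-at first LE) and b; evaluable background series
into c (PE anywhere) and d. A series is evaluable for PEs of level L iff at
least one event of level L activated within its window (≤ first LE time for
LE-series; anywhere for background) — otherwise nothing could have been
detected there and the series is treated as absence of evidence. The same
rule applies uniformly when LE is another event (TF analyses) rather than
the adverse outcome.

p = P(X ≥ a) under the central hypergeometric with the observed margins
(the one-sided Fisher's exact test of the null "odds ratio ≤ 1"); the
reported odds ratio is the conditional MLE of Fisher's noncentral
hypergeometric (∞ when b·c = 0 with a·d > 0; undefined for zero-margin
tables, which report p = 1 and are flagged untestable). Ties at identical
timepoints count as concordant under the default `before_or_at` relation; a
strict `before` mode exists. The exact test is validated against exhaustive
enumeration for every table with margins ≤ 12, and its conservativeness
(type-I ≤ nominal) on a null study.

Raw p-values are the primary screen (threshold 0.05), with BH-adjusted q
within each (level, LE) family reported alongside: the screening convention
is kept for fidelity to the single-screen practice the pipeline reproduces,
while q makes a stricter analysis available. `median_max_abs_effect` is the
median, over LE-series where PE is concordant, of the maximum |effect| at
qualifying timepoints before-or-at LE; series without the PE contribute
nothing (not zero).

## TF regulation mode and cascades

For each directional TF event with both a regulon-activity and an
expression enrichment result, the qualifying series are the adverse series
where activity precedes LE. `strict_before_freq` is the fraction of those
where expression first-activates strictly before activity;
`inclusive_freq` allows ties. Modes:

- **induced** — both enrichments significant (expression events already
  carry the |logFC| > 0.5 criterion) and strict evidence in ≥ 1 series;
- **counter_evidence** — both significant but expression never at or
  before activity (the signature of post-translational activation, e.g.
  ligand-activated nuclear receptors);
- **post_transcriptional** — activity significant without significant
  expression, or both significant with same-time-only evidence (ties alone
  are weaker than induction; both frequencies stay on the record so the
  distinction is auditable);
- **expression_only** — excluded from the graph (expression change without
  activity change indicates, at most, later pathogenesis);
- **untestable** — no expression measurement for the TF.

The cascade graph keeps a prior edge between two significantly enriched
events when (i) node directions match the edge sign (positive edge: same
direction; negative: opposite), and (ii) the source first-activates
before-or-at the target in ≥ `edge_min_freq` (default 20%) of the adverse
series where the target occurs before-or-at LE. The target-conditional
denominator was chosen because an edge can only be temporally supported
where its consequence is observed; both counts and the denominator are
edge attributes, so the all-adverse-series alternative can be recomputed
from the output. TF→target edges additionally require the target TF to be
induced and are routed through the target's expression event, with an
explicit expression → activity "induction" edge (the central-dogma step).
Strict-before support is carried as an attribute, never used as a filter.

## Time dependence

Per adverse series, Spearman's ρ between time and effect (at every
measured timepoint, significant or not — correlation targets progression,
not activation), with (0 h, effect 0) prepended on the assumption of no
treated-control difference before dosing. Midranks handle ties. For ≤ 9
points (the 8-timepoint design plus anchor) the two-sided p is exact: the
permutation distribution of the rank statistic is enumerated once per
rank-multiset and cached; beyond 9 points the t-approximation is used.
Constant trajectories have undefined ρ and are skipped with a log entry.

An event is *consistent* iff ≥ 1 series is significant at
`per_series_alpha` (default 0.05, two-sided — both conventions the
literature leaves open are parameters) and all significant series agree in
sign. Only then is Fisher's combined probability test applied, pooling the
two-sided p of **all** adverse series with defined ρ, not only the
significant ones (χ² = −2Σln p on 2k df; zero p-values are clamped to the
smallest positive float and logged). The joint table classifies events into
both / concordant-only / dependent-only / neither quadrants — concordance
and dependence are distinct properties and either can hold alone.

## Synthetic data

The generator emulates the repeat-dose design: default timepoints 3, 6, 9,
24, 96, 192, 360, 672 h; 3 treated + 3 vehicle-control replicates per
compound and timepoint; baseline expression N(μ_g, σ²) with μ_g ~ N(7, 1)
and σ = 0.5 on the log2 scale — a realistic within-group microarray
variability. Planted gene-set events shift member genes by a configured
effect from a configured onset onward: at the planted onset in penetrant
adverse series, at a random onset in background series at the background
rate. Effects enter at the gene level, so scoring and testing are exercised
end-to-end; `shortcut_activations` is a score-level shortcut for fast unit
tests. Planted TF events stagger the TF's own transcript (expression onset)
at least one timepoint before the regulon (activity onset) so strict-before
induction evidence is recoverable; same-time planting exercises the tie
path. Adverse series follow configured toxscore trajectories (the default
finding crosses "null"/"low" at 192 h and "high" later); background series
carry no findings, and the adverse flag mirrors — rather than reimplements —
the external expert annotation.

Two deliberate departures from a pure textbook null: decoy sets and decoy
TFs activate at an outcome-independent rate (default 10% per series, random
onset and direction) because real non-adverse compounds also perturb
expression — without this bystander biology the evaluability rule would
empty the background margin; and the type-I study plants single-gene events
at an equal, outcome-independent rate in every series so null confusion
tables are informative rather than degenerate. In the planted preset the
pathway event uses effect 2σ (penetrance 0.8, background rate 5%) and the
three cascade TFs use 3σ: a single transcript detected at 3-vs-3
replicates needs a larger shift than a 10-gene set, and the strong,
sustained expression changes of induced TFs are the scenario the cascade
stage targets.

What the generator does **not** emulate: probe-level and batch effects,
correlated gene-gene noise, dose–response structure, pharmacokinetics,
missing timepoints, or heterogeneous finding vocabularies. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability under the stated design, not robustness to every artefact of
real array data.

## Numerical choices

- Strict inequalities at every threshold (FDR, |logFC|, toxscore).
- `before_or_at` is the default temporal relation everywhere; ties count as
  concordant.
- Exact-test p via the hypergeometric survival function; conditional-MLE
  odds ratio via root-finding on the noncentral hypergeometric likelihood.
- Trigamma inversion by Newton iteration with the usual asymptotic
  initialisations; negative moment estimates of the prior variance yield
  d₀ = ∞ (complete shrinkage).
- Exact Spearman p uses a tolerance of 1e-9 on the rank statistic when
  counting equally extreme permutations, avoiding spurious strictness at
  floating-point ties.
- Writers emit floats at %.17g (expression) or %.10g (result tables);
  readers parse with round-trip float precision, so write∘read is
  bit-exact and identical seeds give byte-identical outputs.

## Known limitations

- First-activation times are limited by the measurement grid; onset between
  timepoints is detected late, and low power at onset delays detection —
  both bias against, never toward, concordance.
- The evaluability rule conditions on same-level activity and can shrink
  margins drastically when few entities of a level exist; untestable events
  are flagged rather than dropped.
- Raw-p screening across thousands of events is liberal by construction;
  the q column is provided for stricter use.
- The cascade stage only recovers edges present in the prior network and
  inherits its biases; support frequencies are descriptive, not tested.
- Problem sizes in the test suite and acceptance script (40 adverse + 100
  background series, 200 candidate sets, 1000-gene null study) are the
  package's validation design — large enough for stable ranks and rates at
  single-CPU scale while exercising every stage end-to-end.
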