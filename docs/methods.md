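# Methods

## The ontology model

An isolation-environment ontology is a forest: every class has at most
one parent, and the roots default to six exclusive top categories
(animal, plant, environmental, fungal, industrial products, victuals).
Single inheritance is enforced — an OWL input in which a class declares
two named superclasses is rejected with an error naming the class rather
than coerced, because downstream closure counts and exclusive
order-by-category tables assume a forest. Constructs outside the
supported OWL subset (restrictions, equivalence axioms, anonymous
classes) are reported as warnings, never silently dropped.

A strain instance stores only its *direct* (most specific) classes;
memberships in ancestors are always derived by closure, never
materialised, so the two can never disagree. A strain may carry several
direct classes only if they lie on one root-to-leaf path or are all
leaves (a multi-part environment description); anything else is a
validation error. Relational assertions (`property(strain, target
class)`) use closure on the *target*: a relation to *beetle* makes the
strain a relational member of *animal*. Relational membership queries
accept any property by default and can be filtered to one property;
both relational and modifier properties participate, since nothing in a
membership query distinguishes them.

Property identifiers must be XML-name-safe slugs because they serve as
RDF/XML predicates; the human-readable form ("is from animal on plant")
lives in the label. Class and strain ids are free strings
(whitespace-trimmed, case-sensitive) and are percent-encoded into IRIs.
The TSV dialect is three files sharing a stem (assignments, class table,
property table), UTF-8, `|`-separated multi-values, relation triples as
`property_id->target_class_id`; it round-trips losslessly against the
OWL representation, and the OWL writer emits triples in sorted order so
equal ontologies serialise to identical bytes.

Labelling tasks are declarative: include classes, include relational
terms `(property, target)` with a `*` wildcard for "any property",
then exclusions of the same two shapes, applied after inclusions. This
is the mechanism behind environment-definition refinements such as
"plant class *or* relationally from plant, but not decay-associated":
relational inclusion pulls in strains isolated from, say, insects on
plants, and the decay exclusion removes strains from dead plant matter.

## Feature pipeline

KO (KEGG Ortholog) features are strictly binary presence/absence; copy
number is out of scope. The prevalence filter removes KOs carried by
strictly less than the threshold fraction (default 20%) of strains — a
KO at exactly the boundary stays. Balancing downsamples the majority
class uniformly without replacement (seeded); the minority class is
never touched. Splits are stratified 80/20 with
`len(test) = round(test_fraction · n)`; stratification guarantees both
classes in the test fold, without which AUC would be undefined.

## Forest protocol

Hyperparameters follow the ranger vocabulary: `mtry` (features
considered per split) maps to scikit-learn `max_features`, `min_n`
(minimum number of data points for a node to be split) to
`min_samples_split`. Tuning is a two-stage grid search: stage 1 over
mtry ∈ {√p, p/10, p/3} × min_n ∈ {2, 5, 10}, stage 2 over the stage-1
optimum scaled by 0.75 and 1.25, rounded, deduplicated and clamped
(mtry ∈ [1, p], min_n ≥ 2). Each grid point is scored by AUC on a
withheld 20% validation fold; `TuningConfig.n_resamples` averages the
validation AUC over several different 80/20 folds, which stabilises the
selection on weak-signal problems where a single fold's AUC noise
(±0.04 at ~130 validation samples) can otherwise dominate the choice.
Ties break toward smaller parameters, deterministically. Tuning is done
once per task and the selected pair reused across all iterations.

Each iteration draws a fresh balanced set (seeded `base_seed + i`) and a
fresh stratified split, fits a forest on the training fold only, and
evaluates AUC (rank-sum form of the Mann–Whitney U statistic; midranks,
so ties count ½) and TPR at a 0.5 score threshold on the test fold only.

Permutation importance is measured out of bag by default: for each
tree, its out-of-bag samples are scored with and without each feature
permuted (fresh permutation per tree) and the per-tree AUC drops are
averaged over all trees, features unused by a tree contributing exactly
zero — the scheme the ranger package implements. Test-fold and
training-fold variants are available (`importance_data='test'|'train'`);
the training-fold variant is retained for completeness but is
uninformative in practice because in-bag predictions sit at the AUC
ceiling. The test-fold variant is unbiased but noticeably noisier: it
rests on a single permutation over ~130 samples, versus an average over
hundreds of per-tree out-of-bag evaluations.

Two implementation notes. First, only trees that actually split on a
feature can change their prediction when that feature is permuted, so
the importance code re-applies just those trees and reuses all other
per-tree probabilities; this is numerically identical to the naive
permute-one-column-and-repredict loop (asserted in the test suite), and
what makes 25-iteration × 10-replicate studies practical on one CPU.
Second, scores are rounded to 10 decimals before ranking so that
mathematically equal probabilities reached by different floating-point
summation orders tie identically.

Consensus: a KO is flagged when it appears in the per-iteration top-K
importances in at least `ceil(min_frac · n_iterations)` iterations
(defaults K = 1000, min_frac = 0.8, n_iterations = 100, 500 trees).
Top-K ties break by importance descending, then KO id ascending. The
misclassification audit calls a strain consistently misclassified only
if it was wrong in *every* test-fold appearance; appearance counts are
reported so rarely-tested strains are visible.

## Association statistics

Per-KO 2×2 tables (presence × class membership) are tested two-sided
with Fisher's exact test (probability-mass convention: sum over tables
with probability ≤ observed at fixed margins, via scipy). The reported
odds ratio is the unconditional cross-product ad/bc — not the
conditional MLE — with ∞/0 when exactly one of the products is zero and
the record flagged. Pathway enrichment is one-sided hypergeometric
over-representation of the consensus set against the annotated-KO
universe, BH-adjusted across tested pathways; pathways smaller than 3
universe KOs (configurable) are skipped. KEGG pathways whose label ends
in a "– yeast" suffix are removed before testing (any dash variant,
case-insensitive, surrounding whitespace ignored): these pathways are
defined narrowly on one order and under-annotated elsewhere, and the
removal list is logged in the run manifest.

## Synthetic data

The generator emulates a subphylum-scale isolation survey: ~1500 classes
under the six roots grown by uniform random attachment with a depth cap
(default 6), ~1000 strains each assigned one direct class under a root
drawn from a mixture or exact per-root counts, cross-root relational
assertions at a configurable rate (default 0.3), and taxonomic order
labels. KO presence is class-conditional Bernoulli: background KOs get
one prevalence per KO drawn uniformly from [0.25, 0.95] (presence is a
species-level trait, so it is drawn once per KO, not per strain);
planted KOs switch prevalence on the strain's class label, defaulting to
the 87%/66% carrier-rate template over the positive and negative
classes. Every KO belongs to at least one pathway; planted KOs are
concentrated in a dedicated pathway padded with background KOs to a
typical size. Simulation labels are computed *through* the ontology
(closure membership of the positive root plus relational membership),
not copied from the sampling step, so label construction is itself
exercised. A configurable fraction of positive strains receive their
positive status only via a relational assertion, which is what makes
task-redefinition comparisons testable.

What the generator does not model: phylogenetic correlation among
strains (the forests here are phylogeny-naïve, as is the protocol it
implements), KO–KO linkage beyond pathway co-membership, and
annotation error. Passing recovery tests therefore show the pipeline
detects a planted marginal effect of the stated size under independent
strains — not that real yeast data, with its strong phylogenetic
structure, would yield the same power.

## Calibration experiments and problem sizes

The recovery study (`yeastenv.experiments`) simulates 339 positive and
747 negative strains with 2000 KOs and one planted KO at 87%/66%, tunes
once (three-resample validation), and runs 10 independent
simulate-and-fit replicates of 25 iterations each with 100 trees, three
permutation repeats, and the top-K cut at 5% of features. These sizes
are the package's scaled study conditions: they keep a full multi-seed
study around ten minutes on a single CPU while leaving the planted
contrast, sample sizes and feature count at their stated values. The
expected outcome, asserted in the acceptance tests, is the planted KO
consensus-flagged in ≥95% of replicates, the planted pathway ranked
first by enrichment wherever a consensus set exists, and mean test AUC
above 0.55 (a single KO with this contrast carries limited signal — its
theoretical single-feature AUC is ≈0.60). The null control (nothing
planted) must show mean AUC within [0.45, 0.55] and a raw Fisher
significance fraction near the nominal 5%.

## Design choices on open points

- Balancing method (unspecified upstream): uniform downsampling without
  replacement — the simplest scheme consistent with a "balanced data
  set" and with reported class sizes.
- Prevalence denominator: all matrix rows (strains). If strains
  duplicate species, per-species prevalence can be computed by
  collapsing rows before filtering.
- Iterations re-balance per iteration by default; a switch
  (`rebalance_per_iteration=False`) reuses one balanced set with fresh
  splits.
- Exclusive order-by-category tables use the root category of a
  strain's direct classes and refuse overlapping categories;
  non-exclusive tables use closure counts over the full order size and
  can add "(modifier)" rows from relational membership. Published
  non-exclusive tables show denominators that vary within an order;
  this package always reports its denominators explicitly rather than
  guessing the upstream convention.
- A strain may carry multiple unrelated direct classes only as
  co-asserted leaves; mixed-substrate strains should document the
  assignment in `isolation_text`.
- The estimator is scikit-learn compatible (`get_params`/`set_params`,
  fitted attributes with trailing underscores, `predict_proba` from a
  final forest fit on one balanced set) so it composes with pipelines
  and model selection.

## Limitations

- No OWL reasoning: no restrictions, equivalence, or inference beyond
  subclass closure.
- No multi-label modelling over the whole ontology; one binary task per
  run.
- The classifier's probability outputs come from a single final forest,
  not an ensemble over the iteration models.
- Real survey data reach this pipeline through the OWL/TSV readers; the
  package computes census figures (class/property/instance counts,
  class-size queries) from whatever file is supplied and makes no
  assumptions about its size.
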