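# Methods

## Model and assumptions

The package operationalizes one idea: genes whose protein products sit
close to a drug's targets in a physical interaction network are more likely
to modulate the response to that drug, so *pathways* enriched in such genes
make robust, transferable response biomarkers.  The assumptions are that
(i) the PPI network is informative about functional proximity at the
confidence threshold used, (ii) pathway-level expression summaries are more
stable across cohorts than single genes, and (iii) response-relevant
biology is at least partly shared between cohorts treated with the same
drug class.

### Network propagation

The walk runs on the undirected, unweighted graph of links with combined
score strictly greater than the threshold (default 700 of 1000), restricted
to the largest connected component.  Personalized PageRank uses damping
0.85, a restart vector uniform over the seed (target) genes, L1
convergence tolerance 1e−6 and at most 100 iterations (`networkx.pagerank`
defaults; the solver's non-convergence is flagged on the result, never
silent).  Edge scores may optionally be used as walk weights
(`weighted=True`); the default is unweighted because the confidence filter
has already been applied and score magnitudes above it are not calibrated
as interaction strengths.  The top k = 200 genes by stationary mass are
the proximal set; ties at the boundary break by ascending gene symbol so
the selection is deterministic.  Note the threshold predicate is exposed
(`inclusive=True` gives ≥) because community usage of "greater than" is
ambiguous for STRING cutoffs; reproducing a published node/edge count may
require checking both.

### Pathway selection

Over-representation uses the hypergeometric upper tail P(X ≥ k) with
universe N, pathway size K, draw size n (proximal genes inside the
universe) and overlap k, followed by step-down Šidák (Holm–Šidák)
adjustment over all testable pathways jointly; adjusted P < 0.01 selects
the panel.  The universe defaults to the intersection of network nodes and
the union of all pathway genes, so the drawn genes and the urn live in one
population; `network` and `collection` alternatives are exposed.  Pathways
with no gene in the universe cannot be tested and are skipped before
correction (logged).  No pathway-size filter is applied by default.  All
selected pathways are carried forward as classifier features, not only the
top hits.

### ssGSEA scoring

Per sample, genes are ranked by descending expression; the rank statistic
of the gene at position p among N genes is r = N − p + 1, and the
enrichment score of set S is the sum over all positions of
P_hit − P_miss, where P_hit accumulates r^α (α = 0.25) over in-set genes
and P_miss accumulates 1/(N − |S|) over out-of-set genes.  Expression ties
are resolved by ascending gene symbol after a stable sort, which makes
scores platform-independent.  ES is normalized to NES by dividing by the
global range max(ES) − min(ES) over the whole pathways × samples matrix
(no per-sample renormalization), then features are z-scored per row across
the samples of one cohort using the population SD (ddof 0); zero-variance
rows become zeros with a warning.  Standardization is computed once on the
full cohort, before any cross-validation split — its purpose is to put
cohorts on a common scale for across-study transfer, not to be re-estimated
per fold (a per-split option exists).

### Classification

L2-regularized logistic regression (lbfgs) with class weights inversely
proportional to class frequencies.  C is chosen from
{0.1, 0.2, …, 1.0} by stratified inner 5-fold cross-validation maximizing
accuracy; inner folds are unshuffled, ties resolve to the smallest C
(strongest regularization); the model is then refit on the full training
data.  Predicted label = probability ≥ 0.5 (balanced weights make 0.5 the
natural cutoff).  Inner scoring, the cutoff and the grid are configurable;
the defaults are recorded here because the upstream protocol leaves them
open.  Monte-Carlo CV uses stratified 80/20 splits (split i seeded by
`rng_seed + i`), so two feature sets evaluated with one seed see identical
splits — stratification is a deliberate deviation from plain random
splitting, preventing single-class test sets in 35/65 cohorts.  The
ANOVA-F baseline ranks features by the between/within mean-square ratio on
training data only and keeps the top K, with K equal to the size of the
network-selected panel.

### Survival and TMB

Kaplan–Meier product-limit curves with lifelines' log–log (exponential
Greenwood) 95% CI; two-group log-rank with the 1-df chi-square upper tail,
no continuity correction.  "1-year percent survival" reads the KM step
value at t = 365 days (left-continuous step convention; days and the year
length are configurable).  TMB = 2·T + 1·NT, where T counts
nonsense, frame-shift insertion/deletion and splice-site variants, and NT
counts missense, in-frame insertion/deletion and nonstop variants; all
other MAF classes are excluded and counted in the log.  Pre-counted
(sample, T, NT) tables and per-megabase pass-through values are accepted
alongside MAF-like input.  The combined model appends z-scored TMB as one
extra column next to the z-scored pathway activities.

### Score combination and cohort similarity

Combined score = w·netbio + (1−w)·external, w on a 0–0.1–…–1 grid,
evaluated by ROC AUC.  The external score is min-max rescaled to [0, 1]
before blending so that w is comparable across score families (raw
pass-through available).  Cross-cohort transcriptome similarity restricts
both matrices to a gene subset — by default the direct PPI neighbors of the
ICI targets, excluding the targets themselves — and reports, per patient,
the maximum Spearman correlation to any patient of the other cohort, in
both directions (the statistic is asymmetric by construction).  Spearman
ties get average ranks; p-values are exact by permutation enumeration for
n ≤ 9 and use the t approximation otherwise.

## Synthetic benchmark

`synthetic_data` generates the study conditions used by the tests and by
`scripts/acceptance.py`:

* **Graph** — Barabási–Albert preferential attachment (1000 genes, 3 edges
  per new node), scores uniform in (700, 1000]; heavy-tailed degrees mimic
  real PPI topology.  The two target genes are drawn from mid-degree nodes
  (40th–80th percentile) so that recovery exercises propagation rather than
  hub dominance.
* **Pathways** — 50 sets of 15–60 genes; 5 planted sets draw ≥ 80% of
  their members from the targets' ≤ 2-hop neighborhood, the rest draw from
  outside it.
* **Cohorts** — 100 samples, 35% responders (a realistic ICI response rate
  for solid tumors); baseline expression i.i.d. standard normal; planted
  pathway genes shift by ±1.0 SD in responders (one of the five planted
  pathways shifts downward, emulating negatively associated programs);
  overall survival is exponential with responder hazard ratio 0.4 around a
  300-day non-responder median, with 20% independent censoring; mutation
  counts are Poisson (means 5 truncating / 50 non-truncating) with an
  e¹-fold responder multiplier.
* **Cohort pairs** — shared truth, independent samples, 0.8× effect
  attenuation in the second cohort, and five *confounded* non-planted
  pathways per cohort, drawn independently, whose genes are response-shifted
  in that cohort only.  The confounded pathways emulate cohort-specific
  response-correlated biology (batch structure, cohort composition): a
  purely data-driven feature selector finds them in the training cohort and
  loses accuracy across studies, while the network-selected panel is blind
  to them.  This is the generator's mechanism for the documented
  network-vs-data-driven comparison.

What the generator does **not** emulate: count noise and normalization
artifacts (expression is emitted already-normalized), realistic pathway
overlap/ontology structure, correlated gene–gene expression within
pathways beyond the shared mean shift, non-exponential survival, and
covariate-dependent censoring.  Passing the recovery tests therefore shows
the pipeline's statistical machinery is correct under its own assumptions;
it does not certify performance on real cohorts.

## Numerical choices and degenerate inputs

* Deterministic tie-breaks everywhere a ranking feeds a selection:
  ascending gene/pathway/feature name after the primary score.
* Hypergeometric P at k = 0 is exactly 1; adjusted p-values are clamped to
  [p_raw, 1] by construction.
* Constant ES matrices, single-sample z-scoring, empty networks, seedless
  propagation, single-class labels, groups with no events, and constant
  score vectors all raise explicit errors; recoverable degeneracies
  (zero-variance rows, unmapped identifiers, samples without TMB, sets
  without expression overlap) are handled with a logged count or warning
  instead.
* All randomness flows from one root seed; pipeline stages derive their own
  generator as `SeedSequence(root, crc32(stage_name))`, so a stage can be
  re-run in isolation with identical results.  Two runs of the same config
  produce byte-identical artifacts.

## Problem sizes

The default benchmark (1000 genes, 50 pathways, 100 samples per cohort)
was chosen as the smallest configuration at which pathway-activity effects,
multiple-testing behavior and across-study transfer are all
non-trivial; LOOCV with its inner grid search dominates the runtime
(~10⁴ logistic-regression fits per LOOCV, well under two minutes).
Plumbing tests use a further reduced configuration (300 genes, 12 pathways,
30–40 samples).

## Known limitations

* The enrichment universe choice materially affects p-values; the default
  is one defensible option among several, and published pathway counts
  cannot be matched exactly without the same pathway-collection release.
* ssGSEA conventions differ between implementations (weight α, NES
  normalization); this package fixes one convention (α = 0.25, global-range
  NES) and documents it, but scores are not numerically interchangeable
  with other tools.
* The log-rank test assumes proportional hazards for power; with crossing
  survival curves it can miss real differences.
* Across-study prediction assumes per-cohort z-scoring removes scale
  differences; it cannot correct cohort differences in pathway *direction*.
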