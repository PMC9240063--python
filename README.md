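# netbio

Network-based transcriptomic biomarkers for predicting response to
immune-checkpoint-inhibitor (ICI) therapy.

Gene-level biomarkers of immunotherapy response transfer poorly between
patient cohorts.  `netbio` implements a network-guided alternative: instead
of selecting features from the data, it selects **biological pathways that
are network-proximal to the drug's own targets** (PD-1, PD-L1, CTLA-4) in a
high-confidence protein–protein interaction (PPI) network, scores them per
patient with single-sample gene-set enrichment, and uses those pathway
activities as features for response classification, survival stratification
and combination with tumor mutational burden (TMB).  It is aimed at
computational oncologists working with ICI-treated cohorts (expression +
RECIST response + survival) who need biomarker panels that generalize
across studies.

## Method

1. **Network** — a STRING-style scored edge list is filtered to
   high-confidence links (combined score > 700) and restricted to its
   largest connected component.
2. **Propagation** — personalized PageRank with damping factor d = 0.85
   spreads influence from the ICI target genes (restart vector uniform over
   the targets): `s = (1−d)·v + d·W·s`, with `W` the degree-normalized walk
   matrix.  The top 200 genes by stationary probability are the
   *target-proximal* genes.
3. **Pathway selection** — each pathway (GMT gene sets, e.g. Reactome) is
   tested for over-representation of proximal genes with the hypergeometric
   upper tail P(X ≥ k | N, K, n); Holm–Šidák adjusted P < 0.01 defines the
   biomarker panel.
4. **Scoring** — ssGSEA per sample: rank genes by expression and accumulate
   the weighted running sum ES(S) = Σ_i [P_hit(i) − P_miss(i)] with rank
   weight r^0.25; ES is rescaled by the global ES range (NES) and z-scored
   across the samples of a cohort.
5. **Models** — L2-regularized logistic regression with balanced class
   weights, C selected from {0.1,…,1.0} by inner stratified 5-fold CV.
   Protocols: leave-one-out CV, Monte-Carlo CV (stratified 80/20 × 100),
   and across-study prediction.  Survival of predicted responder groups is
   compared by Kaplan–Meier curves and the log-rank test.
   TMB = 2·(truncating) + 1·(non-truncating) mutations can be appended as
   an extra feature, and external per-sample scores can be blended as
   `w·netbio + (1−w)·external`.

A fully synthetic benchmark (`netbio.synthetic_data`) generates a
scale-free PPI graph, pathways planted in the targets' network
neighborhood, and cohorts whose responders carry pathway-level expression
shifts, higher TMB and longer survival — so the whole pipeline is testable
without patient data.

## Worked example

```bash
# write a synthetic benchmark (graph, GMT, two cohorts) and run LOOCV
netbio simulate --seed 5 --out fixtures/
cat > run.yaml <<EOF
links_file: fixtures/network.tsv
gmt_file: fixtures/pathways.gmt
expression_file: fixtures/expression_a.tsv
clinical_file: fixtures/clinical_a.tsv
seed_genes: [G0685, G0729]      # from fixtures/ground_truth.json
out_dir: run_out
rng_seed: 7
EOF
netbio run --config run.yaml --mode loocv
cat run_out/metrics.json
```

which prints (these are the values the run above produces; the file is
indent-formatted):

```json
{
  "accuracy": 0.99,
  "auc_roc": 1.0,
  "auprc": 1.0,
  "confusion": [[35, 1], [0, 64]],
  "f1": 0.9859154929577465,
  "fisher_p": 3.287469621858047e-26
}
```

Read: of 100 synthetic patients, every held-out responder probability ranks
responders above non-responders (AUC 1.0 — the planted pathway signal is
strong); all 35 responders are recovered at the 0.5 probability cutoff with
one false positive, and the association between predicted and observed
response is highly significant (two-sided Fisher exact P ≈ 3×10⁻²⁶).  `run_out/` also contains
the proximal-gene list, the enrichment table, the activity matrix and a
manifest with a content hash per artifact.

The same commands work on real data: a STRING links file (plus an alias
map to gene symbols), an MSigDB GMT, a TMM-normalized expression TSV and a
clinical TSV with `recist` (or `response`) and `os_time`/`os_event`
columns.

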