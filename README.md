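# exhaustclass

Virtual microdissection of bulk tumour transcriptomes: discovery and
validation of an **exhausted immune class (EIC)** — a patient subgroup
whose tumours carry abundant but dysfunctional immune infiltrate, high
inhibitory-checkpoint expression, and poor prognosis despite (or because
of) their immune content.

Bulk RNA-seq mixes tumour, immune and stromal signal in every sample.
Non-negative matrix factorization (NMF) decomposes the expression matrix
V ≈ W·H into additive expression programs ("metagenes"): W holds each
program's gene weights, H each sample's program activity. The pipeline

1. factorizes the cohort with multiplicative updates on the generalized
   Kullback–Leibler divergence D(V‖WH), choosing the rank r by the
   **cophenetic correlation coefficient** of a consensus matrix over
   seeded restarts (argmax over candidates, ties to the smallest rank);
2. identifies the **immune-stromal program** as the cluster with the
   highest combined immune + stromal ssGSEA enrichment and labels its
   samples the EIC;
3. extracts metagene-specific genes by the entropy feature score
   s = 1 + (1/log₂k)·Σ p log₂ p (threshold mean + 3σ), keeps those that
   are differentially expressed between EIC and rest (rank-sum on
   median-of-ratios-normalized log2 counts; FDR < 0.05, |log2FC| ≥ 1),
   and freezes them as the **classifier gene set**;
4. scores any cohort by ssGSEA enrichment of the classifier (the **EIC
   score**) and evaluates it by ROC/AUC, survival association
   (Kaplan–Meier, log-rank, multivariate Cox with 60-month truncation),
   ICB-responder comparison, differential promoter methylation
   (|ΔΒ| > 0.2, FDR < 0.05) with methylation–expression correlation, and
   genomic-burden contrasts.

A synthetic-cohort generator with a full ground-truth record
(expression + survival + methylation + burden + ICB response) makes every
stage testable by parameter recovery at desk scale. It is first-class,
seeded, and documented in `docs/methods.md`.

## Worked example

```python
from exhaustclass import simulate, pipeline, eic
from exhaustclass.io import GeneSet, GeneSetCollection

bundle = simulate.simulate_cohort_bundle(seed=11)        # 2000 genes x 200 samples
truth = bundle["truth"]
signatures = GeneSetCollection([
    GeneSet(name, "", frozenset(genes))
    for name, genes in truth.planted_signature_genes.items()])

art = pipeline.discover(bundle["expression"], signatures,
                        clinical=bundle["clinical"],
                        methylation=bundle["methylation"],
                        burden=bundle["burden"],
                        seed=123, n_runs=12, max_iter=400)
s = art["report"]["stages"]
print(s["rank_selection"]["best_k"])        # 4      (planted k recovered)
print(s["labelling"]["n_eic"])              # 60     (planted 30% of 200)
print(s["classifier"]["n_classifier_genes"])# 30
print(round(s["roc"]["auc"], 3))            # 1.0
print(round(s["burden"]["score_tmb_r"], 3)) # -0.043 (score independent of TMB)
```

The numbers above are the output of this exact snippet: the four planted
expression programs are recovered, the 60 planted EIC samples are
re-identified from the immune/stromal enrichment of their cluster, the
30 immune-stromal marker genes survive the differential-expression
filter, the resulting EIC score separates the classes perfectly, and the
score is uncorrelated with tumour mutational burden (mutations were
planted class-independent). A held-out cohort drawn from the same truth
(`simulate.resimulate_expression`) scored with the frozen classifier
gives AUC ≥ 0.9 — the internal-validation design.

## Command line

```bash
exhaustclass simulate --seed 1 --outdir sim/          # full synthetic bundle
exhaustclass nmf --expression sim/expression.tsv --k 4 --outdir nmf/
exhaustclass score --expression sim/expression.tsv --gmt sim/signatures.gmt --out scores.tsv
exhaustclass discover --config config.yaml --outdir run/   # full training pipeline
exhaustclass predict --config config.yaml --classifier run/classifier.gmt --outdir val/
exhaustclass survive --clinical sim/clinical.tsv --labels run/labels.tsv --outdir surv/
exhaustclass methylation --betas sim/methylation.tsv --annotation sim/methylation_annotation.tsv \
    --labels run/labels.tsv --outdir meth/
exhaustclass burden --burden sim/burden.tsv --labels run/labels.tsv --out burden.json
```

`discover` reads a YAML config naming the expression TSV, a GMT with
signatures tagged `immune`/`stromal`, and optional clinical, methylation
and burden tables; it writes labels, the classifier GMT, score tables and
a versioned JSON report that echoes every parameter and derived seed.

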