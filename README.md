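# stagesig

Stage-signature discovery for ordered carcinogenesis series.

Bronchial squamous-cell carcinogenesis progresses through an ordered series
of histological stages (normal epithelium → metaplasia → dysplasia grades →
carcinoma in situ → invasive carcinoma).  `stagesig` implements, as a tested
and reusable library, a discovery pipeline for small gene panels that
separate those stages from whole-genome expression profiles:

1. **Differential expression** — each non-control stage is contrasted
   against the pooled control group with a moderated two-sample t
   (empirical-Bayes variance squeeze `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)`,
   hyperparameters by method-of-moments on the log variances),
   Benjamini–Hochberg adjustment, a signed fold-change filter
   (|FC| > 1.5, p < 0.05), and a union merge across contrasts.
2. **Network gatekeepers** — the merged gene list induces a subnetwork of a
   cleaned protein–protein interactome; per node the clustering centrality
   `C_i = 2E_i / (k_i(k_i−1))` is computed exactly, and *gatekeepers* are
   the nodes with `C_i = 1` (integer test `2E_i = k_i(k_i−1)`, degree ≥ 2):
   sparsely connected proteins whose few neighbors are mutually connected
   hubs.
3. **Signature reduction** — a softmax multinomial logistic regression of
   the 8 stages is fitted to all genes (L2-regularized, per-gene z-scored
   features); coefficients are standardized jointly across class × gene
   entries and genes whose standardized coefficient magnitude exceeds
   0.78 SD are kept; train-and-select is applied twice
   (all genes → hundreds → ~15).
4. **Random-signature null** — the signature's macro-averaged Jaccard index
   (per class `TP/(TP+FP+FN)`, plus plain accuracy) is compared with the
   same protocol applied to random gene sets of equal size.
5. **Enrichment** — Fisher exact over/under-representation of a gene list
   (e.g. the gatekeepers) against a GMT gene-set collection, with BH-FDR
   across the tested sets.

A seeded synthetic-data module generates expression matrices with planted
stage-ramp genes on a co-expression-module background, and scale-free-ish
interactomes with planted hubs and gatekeepers, so every stage of the
pipeline is exercisable and testable offline.

## Worked example

`examples/03_signature_reduction.py` simulates the default study conditions
(2000 genes, 15 planted stage-ramp genes, 8 stages with per-stage sample
counts 13, 14, 15, 13, 13, 12, 13, 14) and runs the two-round reduction:

```
round 1: 2000 -> 275 genes
round 2: 275 -> 15 genes
planted genes in final signature: 15/15 (precision 1.00)
signature model on training data: accuracy 1.000, macro-Jaccard 1.000
```

The reduction shrinks 2000 candidates to exactly the 15 planted genes; the
signature classifier then reproduces every training label.
`examples/04_random_null.py` puts that score in context:

```
observed macro-Jaccard: 1.000
null over 100 random 15-gene sets: median 0.196, max 0.606
empirical p = 0.0099 (the observed signature beats every random set)
```

The other examples cover DGE recovery (`01`), gatekeeper detection (`02`),
enrichment (`05`), and the end-to-end pipeline with its reproducibility
manifest (`06`).  A thin CLI mirrors the stages:

```bash
stagesig run-all --set seed=0 --set out_dir=run0
stagesig gatekeepers --set edge_list_path=edges.tsv
```

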