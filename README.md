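# tissuenet

Tissue-specific probabilistic functional gene networks for the laboratory
mouse (or any organism with ontology annotations and curated expression
calls), with network-based phenotype gene prioritization and cross-network
comparison.

Most data integration treats "functional relationship" as a single,
organism-wide notion. But two proteins can only cooperate in a biological
process where both are present, and many disease phenotypes are confined
to particular tissues. `tissuenet` builds one functional network *per
tissue* by restricting the training signal — not the evidence — to gene
pairs expressed in that tissue, and then exploits the per-tissue networks
to rank candidate genes for tissue-linked phenotypes and to ask which
genes rewire between tissues.

It is aimed at computational biologists who have: an ontology of
biological processes with gene annotations (for gold standards), curated
tissue expression calls, and any number of heterogeneous pairwise evidence
sources (co-expression, interaction screens, transferred networks,
phenotype co-annotation).

## The model

**Integration.** For a gene pair (i, j) with per-dataset evidence E_k, the
posterior probability of a functional relationship FR is a regularized
naive Bayes classifier, in log-odds form

```
logit P(FR=1 | E)  =  logit P(FR=1)  +  Σ_k  w_k · ln [ P(E_k | FR=1) / P(E_k | FR=0) ]
```

Continuous evidence is discretized into equal-frequency bins; the
per-bin likelihoods are learned from a gold standard with Laplace
smoothing. Gold-standard positives are pairs co-annotated to a *specific*
process term (fewer than 200 annotated genes after propagation); negatives
are pairs where both genes are specifically annotated but share no
specific term. A tissue gold standard keeps only pairs whose genes are
both called expressed in the tissue by curated low-throughput assays.

**Regularization.** Co-expression datasets overlap heavily in information,
violating naive Bayes' independence assumption. For each such dataset k,

```
r_k = Σ_{l≠k} I(k, l) / H(k),        w_k = 1 / (1 + r_k)
```

where I is mutual information between binned score distributions over
shared pairs and H is the dataset's entropy; a dataset duplicated once is
down-weighted to ~1/2, an independent one keeps w = 1.

**Phenotype prioritization.** A phenotype term is mapped to a tissue by
case-insensitive substring match of term names (ties resolved by
cross-validated network AUC). Genes annotated to the term or a descendant
are positives; each gene's features are its network connection weights to
the positive genes; a linear SVM with class-asymmetric cost j is trained
under 0.632 bootstrap bagging, scoring training genes by their median
out-of-bag value and candidates by their median over all bootstraps.

**Cross-network comparison.** Between networks X and Y with priors P_x,
P_y, a gene's connectivity change is

```
D(i) = Σ_n | X_in / P_x  −  Y_in / P_y |
```

with absent edges imputed at the prior. Top changed genes are tested for
ontology-term enrichment (one-sided hypergeometric, Benjamini–Hochberg).

## Worked example

Everything below runs on a synthetic compendium with planted structure —
12 co-functional modules (9 tissue-restricted, 3 constitutive) across 3
tissues, observed by three tissue-context co-expression datasets and one
weaker compendium-wide dataset:

```python
from tissuenet import generate, run_integrate, run_predict
from tissuenet.synth import tissue_recovery_config

cfg = tissue_recovery_config(seed=1)
bundle = generate(cfg)
integ = run_integrate(bundle.datasets, bundle.ontology,
                      bundle.direct_annotations, bundle.calls,
                      max_term_size=cfg.gold_max_term_size, seed=1,
                      for_phenotype_prediction=True)
for tag in sorted(integ.cv):
    print(f"{tag}: CV AUC = {integ.cv[tag].auc:.3f}")

term = sorted(bundle.phenotype_names)[0]
preds = run_predict(integ, bundle.phenotype_ontology,
                    bundle.phenotype_annotations, bundle.phenotype_names,
                    bundle.tissue_names, [term], n_bootstraps=100, seed=1)
pred = preds[0]
print(f"{term} ({bundle.phenotype_names[term]}) -> {pred.tissue}")
for tag, auc in pred.auc.items():
    print(f"  out-of-bag AUC ({tag}): {auc:.3f}")
```

prints

```
GLOBAL: CV AUC = 0.750
MA:0000000: CV AUC = 0.823
MA:0000001: CV AUC = 0.813
MA:0000002: CV AUC = 0.801
SMP:0000001 (synthetic tissue 00 dysfunction) -> MA:0000000
  out-of-bag AUC (MA:0000000): 0.994
  out-of-bag AUC (GLOBAL): 0.943
```

Reading the numbers: three-fold pair-level cross-validation shows every
tissue-trained model recovering its held-out tissue gold standard better
than the globally trained model recovers its own (0.80–0.82 vs 0.75) —
tissue restriction concentrates the training signal on the evidence that
matters there. The phenotype "synthetic tissue 00 dysfunction" maps to
tissue `MA:0000000` by substring match; the bagged network-feature SVM
recovers the planted phenotype genes nearly perfectly from the mapped
tissue network (out-of-bag AUC 0.994) and less well from the global
network (0.943).

The same pipeline is scriptable from the shell:

```bash
tissuenet simulate --config synth.yaml --out bundle/
tissuenet integrate --config run.yaml --out networks/
tissuenet predict --config run.yaml --phenotype SMP:0000001 --out pred/
tissuenet compare --a networks/network_MA_0000000.tsv \
                  --b networks/network_GLOBAL.tsv --config run.yaml \
                  --top 100 --out cmp/
```

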