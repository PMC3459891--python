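# Methods

This note documents the models and procedures implemented in `tissuenet`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where more than one reading was defensible.

## Gold standards

Annotations are propagated along is_a/part_of edges of the process
ontology before anything else; every downstream count uses propagated
sets. A term is *specific* when fewer than `max_term_size` genes
(default 200) are annotated to it post-propagation — so a gene annotated
only to a child counts toward every ancestor's size. Positives are pairs
sharing at least one specific term; negatives are pairs where both genes
hold at least one specific term but share none. Pairs are unordered,
stored in canonical lexicographic orientation, and never include a gene
with itself.

A tissue gold standard is the global one filtered to pairs whose genes
are both present in the tissue's curated expression calls. Expression
calls are taken at face value: absence of a call is treated as unknown,
not as absence of expression, and assay-class filtering is available but
off by default. Tissues are ranked for selection by expressed-set size,
ties broken lexicographically.

## Evidence processing

- **Co-expression**: Pearson correlation per gene pair over
  pairwise-complete samples (at least `min_samples = 3` joint
  observations), Fisher z-transformed with the correlation clamped to
  1 − 1e-6 in absolute value so atanh stays finite, then standardized to
  mean 0 / sd 1 over the dataset's emitted pairs. Zero-variance profiles
  yield no pairs.
- **Interactions**: binary presence per experiment type; types with fewer
  than 1000 distinct pairs are merged into a single `grouped_small_types`
  dataset so each dataset's likelihoods are estimated from enough pairs.
- **Ortholog transfer**: target pairs receive the arithmetic mean of all
  source-pair scores mapping onto them; pairs collapsing to a single
  target gene are dropped.
- **Phenotype/disease similarity**: S(i,j) = Σ_k a_ik·a_jk / N_k, the
  simplest form in which co-occurrence of a rarely annotated phenotype
  outweighs a broadly annotated one. A 1/n normalization over the total
  phenotype count changes no ranking and is available as an option.
  These datasets are tagged circularity-sensitive and are excluded
  structurally whenever integration is run for phenotype prediction —
  the anti-circularity rule is enforced by the dataset tag, not by
  convention.

## Integration

Continuous datasets are discretized into equal-frequency bins (default
5); binary datasets pass through as {0, 1}. Conditional probability
tables use Laplace smoothing with pseudo-count α = 1; the prior defaults
to the gold-standard class balance and can be overridden (networks meant
to be compared with the connectivity-change statistic should share a
prior; see below). Evidence absent for a pair is marginalized out of the
product rather than modeled as a MISSING bin: dataset coverage varies by
orders of magnitude and a MISSING likelihood would largely encode
ascertainment. A MISSING bin remains available behind a flag.

The regularized contribution of dataset k multiplies its log-likelihood
ratio by w_k = 1/(1 + r_k), where r_k is the ratio of the dataset's
summed pairwise mutual information with the other co-expression datasets
to its own entropy. Three properties motivated this form over exponent or
shrinkage variants: it reduces to plain naive Bayes for independent
datasets (r = 0), halves the contribution of an exactly duplicated
dataset (I = H gives w = 1/2), and is continuous in between. MI is
estimated from empirical joint bin frequencies (natural log) over the
pairs present in both datasets, using the same bins as the likelihoods; a
single-bin dataset has zero entropy, nothing to regularize, and keeps
w = 1 with a warning. Only continuous (co-expression-like) datasets are
regularized; interaction and transferred datasets keep w = 1.

Networks score every pair with at least one observed evidence value;
tissue networks are restricted to the tissue's expressed-gene universe.
Scoring pairs with no evidence at the prior is available but off by
default.

## Evaluation

Cross-validation is pair-level, k = 3 by default, class-stratified
(the degenerate folds a small tissue gold standard can produce otherwise
are not worth the fidelity of unstratified sampling; unstratified mode is
available). Discretization is fit once on the unlabeled score
distributions; per fold, likelihoods and regularization weights are
re-learned on the training folds. AUC uses midrank tie handling and is
verified against the Mann–Whitney statistic; precision-recall curves are
computed at every distinct threshold, and precision-at-recall reports the
most stringent threshold reaching the requested recall.

For tissue-vs-global comparisons, folds are drawn on the *tissue* gold
standard and the globally trained model is fit on the global gold
standard minus the held-out pairs, so both models are scored on the same
held-out set and the two AUCs differ only by training regime.

## Phenotype prioritization

Substring mapping is case-insensitive and uses term names only (not
definitions): a phenotype maps to every tissue whose name is contained in
the phenotype's name, resolved by highest cross-validated tissue AUC.
Positives are genes annotated to the term or any descendant (allele
identifiers collapse to genes at load time); fewer than 3 positives
refuse to train. Negatives default to all remaining network genes; a
seeded subsample at a configurable ratio is available, in which case the
leftover genes are scored as unknowns but never trained on.

The SVM is a linear soft-margin classifier (C = 1 by default, features
used as-is since network scores live in [0, 1]) with positive-class cost
j = |negatives|/|positives| by default, balancing total class cost.
Bagging draws |training| examples with replacement per bootstrap
(B = 100 by default); a bootstrap missing a class is redrawn, at most 10
times. Training genes are scored by the median of their out-of-bag
decision values and unknowns by the median over all bootstraps. When B is
small enough that some training gene was drawn into every bootstrap,
extra bootstraps are run until every training gene has at least one
out-of-bag value, so out-of-bag evaluation is always defined.

## Cross-network comparison

The per-gene change score sums |X_in/P_x − Y_in/P_y| over all partners
present in either network; an absent edge is imputed at that network's
prior (ratio 1) so sparsity differences alone do not register as change.
"Fold change over prior" is read as the linear ratio; a log-ratio variant
(identical under the linear reading, different under log) is behind a
flag. Because the linear ratios scale as 1/prior, comparing two networks
built with different class-balance priors manufactures change on every
strong shared edge; networks intended for comparison should therefore be
built with a common prior override, which is how the comparison
experiments here run.

Enrichment of the top changed genes (default top 100, ties lexicographic)
is a one-sided hypergeometric test per overlapping term with
Benjamini–Hochberg adjustment across tested terms; the background is the
union of genes in either network, and a term-size bound is available to
keep near-universal terms (ontology roots) out of the test. Both raw p
and adjusted q are reported.

## Synthetic compendia

The generator plants the structure the integration framework assumes and
nothing more: disjoint co-functional modules drive both ontology
co-annotation (one small term per module under one root, so module pairs
become gold positives and cross-module pairs negatives) and evidence
scores. Per continuous dataset, a co-module pair's score is drawn from
N(2, 1) with probability β (the dataset's planted informativeness) and
from N(0, 1) otherwise; binary datasets flag co-module pairs at rate β
against a low background. Redundant datasets are noisy copies of a
partner. Tissue-restricted modules have their genes called expressed only
in their tissue, and their co-functionality is visible only to datasets
whose context includes that tissue — the premise that co-functionality
requires co-presence, encoded generatively. Phenotypes are module gene
sets with names embedding their tissue's name so that substring mapping
has a planted answer.

What this does *not* emulate: realistic ontology topology (one root, one
level), probe-level microarray noise, correlated evidence beyond exact
copies, annotation bias, and gene multifunctionality (modules are
disjoint). Passing tests therefore demonstrate that each algorithm
recovers the structure it assumes at realistic sizes and noise levels —
not performance on real compendia, which depends on how far real data
deviate from these assumptions.

Study conditions frozen for the recovery experiments:

- *Informativeness ladder*: 2000 genes, 40 modules × 15 genes, five
  compendium-wide datasets at β = 0.9, 0.7, 0.5, 0.3, 0.1; learned mean
  |LLR| per dataset is rank-compared to the planted order (10 seeds).
- *Redundancy*: one β = 0.6 dataset plus a copy with N(0, 0.01²) noise;
  both should weigh ≈ 1/2.
- *Tissue recovery*: 300 genes, 12 modules × 10 (9 tissue-restricted
  across 3 tissues), three tissue-context datasets (β = 0.7) plus one
  compendium-wide (β = 0.3); paired CV on the tissue gold standard
  (10 seeds). Also the base for phenotype prioritization (B = 100).
- *Network comparison*: the same design scaled to 600 genes and 18
  modules with 4000 background evidence pairs, so a top-100 change list
  is a small fraction of the network.

These sizes were chosen as the smallest at which the planted effects are
comfortably outside sampling noise; they keep the full recovery suite at
around a minute on one CPU.

## Numerical notes and edge cases

- Correlations are clamped before atanh at |ρ| = 1 − 1e-6.
- Equal-frequency bin edges come from `numpy.quantile`; datasets with
  fewer distinct values than requested bins get fewer bins, and a
  constant dataset collapses to one bin with zero LLR after smoothing.
- CPT columns are validated to sum to 1 within 1e-9 and to be strictly
  positive after smoothing.
- All pair maps key on canonical sorted pairs; querying (i, j) and (j, i)
  is identical by construction.
- Seeds: every stochastic stage takes an explicit seed; the pipeline
  derives per-stage seeds from one root seed via SHA-256 of the stage
  name, so stage results are independent of the order stages run in.
- Degenerate inputs fail loudly and early: unknown ontology terms name
  the term, missing tissues name the tissue, an empty gold-standard class
  names the class; an empty annotation set yields an empty gold standard
  with a warning rather than an error.

## Known limitations

- The naive Bayes independence assumption is only mitigated, not removed,
  by MI regularization; strongly dependent non-co-expression datasets are
  not down-weighted.
- Substring phenotype-tissue mapping misses synonym and part-of
  relationships ("renal" vs "kidney"); the mapping table is replaceable.
- The SVM is linear with fixed C; no per-phenotype hyperparameter search.
- Connectivity-change scores depend on the shared-prior convention noted
  above; comparisons across priors are not meaningful under the linear
  ratio reading.
- Scaling is in-memory and single-process; pair maps are Python dicts,
  adequate to a few million scored pairs.
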