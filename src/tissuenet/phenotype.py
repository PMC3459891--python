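"""Network-based phenotype gene prioritization.

Phenotype terms are mapped to tissue networks by case-insensitive substring
matching of term names.  For a phenotype, genes annotated to the term or
any descendant are positives; a linear support-vector machine is trained on
features x[g][p] = network connection weight from gene g to each positive
gene p, with an asymmetric misclassification cost j for positives.  Models
are trained under 0.632 bootstrap bagging: each bootstrap resamples the
training set with replacement, out-of-bag training genes get unbiased
evaluation scores, and every gene's final score is the median over
bootstraps (out-of-bag medians for training genes, all-bootstrap medians
for unknown genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.svm import SVC

from ._util import log
from .bayes import FunctionalNetwork
from .evaluation import EvaluationResult, evaluate_scores
from .gold import AnnotationSet, Ontology


@dataclass
class PhenotypeTissueMap:
    """Phenotype term -> chosen tissue term (substring method)."""

    mapping: Dict[str, str]
    method: Dict[str, str]
    unmapped: List[str]
    ambiguity_log: Dict[str, List[str]] = field(default_factory=dict)


@dataclass
class SVMProblem:
    """Features and labels for one phenotype's classifier.

    Rows of ``x`` are genes (training positives, training negatives, then
    unknowns); columns correspond 1:1 to the positive genes.
    """

    genes: List[str]
    positive_genes: List[str]
    negative_genes: List[str]
    x: np.ndarray
    y: np.ndarray  # +1 / -1 for training genes, 0 for unknown genes

    def __post_init__(self) -> None:
        if self.x.shape != (len(self.genes), len(self.positive_genes)):
            raise ValueError("feature matrix shape mismatch")
        if self.y.shape != (len(self.genes),):
            raise ValueError("label vector shape mismatch")

    @property
    def training_idx(self) -> np.ndarray:
        return np.nonzero(self.y != 0)[0]

    @property
    def unknown_idx(self) -> np.ndarray:
        return np.nonzero(self.y == 0)[0]


@dataclass
class PhenotypeRanking:
    """Bagged per-gene scores for one phenotype."""

    phenotype: str
    scores: Dict[str, float]
    is_training_positive: Dict[str, bool]
    out_of_bag: Dict[str, bool]  # True where the score is an OOB median
    n_bootstraps: int
    seed: int


def map_phenotypes(
    phenotype_names: Mapping[str, str],
    tissue_names: Mapping[str, str],
    cv_auc: Optional[Mapping[str, float]] = None,
) -> PhenotypeTissueMap:
    """Map each phenotype to a tissue by name-substring matching.

    A phenotype maps to every tissue whose lower-cased name occurs as a
    substring of the phenotype's lower-cased name; multiple matches are
    resolved to the tissue whose network has the highest cross-validation
    AUC (``cv_auc``), ties broken lexicographically.  Phenotypes with no
    match are flagged unmapped (callers fall back to the global network).
    """
    mapping: Dict[str, str] = {}
    method: Dict[str, str] = {}
    unmapped: List[str] = []
    ambiguity: Dict[str, List[str]] = {}
    for pterm, pname in phenotype_names.items():
        pl = pname.lower()
        matches = sorted(t for t, tname in tissue_names.items()
                         if tname and tname.lower() in pl)
        if not matches:
            unmapped.append(pterm)
            continue
        if len(matches) > 1:
            ambiguity[pterm] = list(matches)
            if cv_auc is not None:
                matches.sort(key=lambda t: (-cv_auc.get(t, float("-inf")), t))
        mapping[pterm] = matches[0]
        method[pterm] = "substring"
    return PhenotypeTissueMap(mapping=mapping, method=method,
                              unmapped=unmapped, ambiguity_log=ambiguity)


def phenotype_gene_sets(
    annotations: AnnotationSet,
    phen_ontology: Ontology,
    term: str,
    candidate_genes: Optional[Set[str]] = None,
    negative_ratio: Optional[float] = None,
    seed: int = 0,
    min_positives: int = 3,
) -> Tuple[Set[str], Set[str]]:
    """Positive and negative gene sets for one phenotype term.

    Positives are genes annotated (post allele->gene collapse, which the
    annotation loader applies) to the term or any of its descendants.
    Negatives default to all remaining candidate genes; ``negative_ratio``
    draws a seeded random sample of size ratio * |positives| instead.
    """
    closure = {term} | set(phen_ontology.descendants(term))
    positives = {g for g, terms in annotations.propagated.items()
                 if terms & closure}
    if candidate_genes is not None:
        positives &= candidate_genes
    if len(positives) < min_positives:
        raise ValueError(
            f"phenotype {term!r} has only {len(positives)} positive gene(s); "
            f"need >= {min_positives} to train"
        )
    pool = candidate_genes if candidate_genes is not None else annotations.genes()
    negatives = set(pool) - positives
    if negative_ratio is not None:
        rng = np.random.default_rng(seed)
        size = min(len(negatives), int(round(negative_ratio * len(positives))))
        negatives = {str(g) for g in
                     rng.choice(sorted(negatives), size=size, replace=False)}
    return positives, negatives


def build_features(
    network: FunctionalNetwork,
    positives: Sequence[str],
    negatives: Sequence[str],
    candidate_genes: Optional[Sequence[str]] = None,
) -> SVMProblem:
    """Connection-weight features: x[g][p] = network score between g and p.

    Absent edges contribute 0; the diagonal convention x[p][p] = 0 keeps a
    positive gene from trivially identifying itself.  Positives absent from
    the network are dropped (with a warning) rather than yielding all-zero
    columns.
    """
    net_genes = network.genes()
    kept_pos = [p for p in positives if p in net_genes]
    dropped = sorted(set(positives) - set(kept_pos))
    if dropped:
        warnings.warn(f"positives absent from network, columns dropped: {dropped}")
    if not kept_pos:
        raise ValueError("no positive gene present in the network")
    kept_pos = sorted(kept_pos)
    neg = sorted(set(negatives) - set(kept_pos))
    if candidate_genes is None:
        unknown = sorted(net_genes - set(kept_pos) - set(neg))
    else:
        unknown = sorted(set(candidate_genes) - set(kept_pos) - set(neg))
    genes = kept_pos + neg + unknown
    y = np.concatenate([np.ones(len(kept_pos)), -np.ones(len(neg)),
                        np.zeros(len(unknown))])
    x = np.zeros((len(genes), len(kept_pos)))
    for gi, g in enumerate(genes):
        for pi, p in enumerate(kept_pos):
            if g == p:
                continue
            x[gi, pi] = network.get(g, p, 0.0)
    return SVMProblem(genes=genes, positive_genes=kept_pos, negative_genes=neg,
                      x=x, y=y)


def expected_distinct_fraction(n: int) -> float:
    """Expected fraction of distinct examples in a size-n bootstrap: 1-(1-1/n)^n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - 1.0 / n) ** n


def bagged_svm(
    problem: SVMProblem,
    n_bootstraps: int = 100,
    seed: int = 0,
    cost_asymmetry: Optional[float] = None,
    svm_c: float = 1.0,
    max_retries: int = 10,
) -> PhenotypeRanking:
    """Bootstrap-bagged linear SVM scoring of all genes.

    Each bootstrap draws |training set| examples with replacement (the
    0.632 bootstrap), fits a linear soft-margin SVM whose positive-class
    misclassification cost is ``cost_asymmetry`` times the negative one
    (default |negatives| / |positives|, balancing total class cost), and
    scores out-of-bag training genes plus all unknown genes with the signed
    decision function.  Final scores are medians per gene.
    """
    rng = np.random.default_rng(seed)
    train_idx = problem.training_idx
    unknown_idx = problem.unknown_idx
    n_train = len(train_idx)
    n_pos = int((problem.y[train_idx] == 1).sum())
    n_neg = n_train - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the training set")
    j = cost_asymmetry if cost_asymmetry is not None else n_neg / max(n_pos, 1)

    per_gene: Dict[int, List[float]] = {int(i): [] for i in train_idx}
    unknown_scores: Dict[int, List[float]] = {int(i): [] for i in unknown_idx}
    for _ in range(n_bootstraps):
        for attempt in range(max_retries + 1):
            draw = rng.choice(n_train, size=n_train, replace=True)
            boot = train_idx[draw]
            if len(np.unique(problem.y[boot])) == 2:
                break
            log.info("bootstrap missing a class; resampling (attempt %d)", attempt + 1)
        else:
            raise RuntimeError("could not draw a bootstrap with both classes")
        oob = np.setdiff1d(train_idx, boot)
        clf = SVC(kernel="linear", C=svm_c, class_weight={1: j, -1: 1.0})
        clf.fit(problem.x[boot], problem.y[boot])
        if len(oob):
            for i, s in zip(oob, clf.decision_function(problem.x[oob])):
                per_gene[int(i)].append(float(s))
        if len(unknown_idx):
            for i, s in zip(unknown_idx,
                            clf.decision_function(problem.x[unknown_idx])):
                unknown_scores[int(i)].append(float(s))

    # top up: a gene drawn into every bootstrap has no out-of-bag score yet;
    # run extra bootstraps until each training gene has been held out once
    extra = 0
    while any(not v for v in per_gene.values()) and extra < 100 * n_bootstraps:
        extra += 1
        draw = rng.choice(n_train, size=n_train, replace=True)
        boot = train_idx[draw]
        if len(np.unique(problem.y[boot])) < 2:
            continue
        oob = np.setdiff1d(train_idx, boot)
        uncovered = [int(i) for i in oob if not per_gene[int(i)]]
        if not uncovered:
            continue
        clf = SVC(kernel="linear", C=svm_c, class_weight={1: j, -1: 1.0})
        clf.fit(problem.x[boot], problem.y[boot])
        for i, s in zip(oob, clf.decision_function(problem.x[oob])):
            if int(i) in uncovered:
                per_gene[int(i)].append(float(s))
    if extra:
        log.info("ran %d extra bootstrap(s) to cover out-of-bag scores", extra)

    scores: Dict[str, float] = {}
    oob_flag: Dict[str, bool] = {}
    is_pos: Dict[str, bool] = {}
    for i in train_idx:
        g = problem.genes[int(i)]
        vals = per_gene[int(i)]
        if vals:
            scores[g] = float(np.median(vals))
            oob_flag[g] = True
        is_pos[g] = bool(problem.y[int(i)] == 1)
    for i in unknown_idx:
        g = problem.genes[int(i)]
        scores[g] = float(np.median(unknown_scores[int(i)]))
        oob_flag[g] = False
        is_pos[g] = False
    return PhenotypeRanking(phenotype="", scores=scores,
                            is_training_positive=is_pos, out_of_bag=oob_flag,
                            n_bootstraps=n_bootstraps, seed=seed)


def evaluate_phenotype(
    ranking: PhenotypeRanking,
    positives: Set[str],
    negatives: Set[str],
) -> EvaluationResult:
    """AUC / PR of out-of-bag median scores over the training genes."""
    missing = [g for g in (positives | negatives)
               if g not in ranking.scores or not ranking.out_of_bag.get(g, False)]
    if missing:
        raise ValueError(
            f"training genes without out-of-bag scores: {sorted(missing)[:5]}"
        )
    pos = [ranking.scores[g] for g in sorted(positives)]
    neg = [ranking.scores[g] for g in sorted(negatives)]
    return evaluate_scores(pos, neg, tissue=ranking.phenotype or "GLOBAL")
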