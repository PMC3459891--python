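"""Pair-level k-fold cross-validation of integrated networks.

The gold standard is partitioned into k folds (class-stratified by
default); for each fold a model is trained on the remaining folds and the
held-out pairs are scored with its posterior.  AUC and precision-recall are
computed over the pooled held-out scores.  AUC here is the probability that
a random positive pair outranks a random negative one (Mann-Whitney with
midrank ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score

from ._util import Pair
from .bayes import (DiscretizationScheme, fit_discretization, learn_cpts,
                    posterior, regularization_weights)
from .evidence import EvidenceDataset
from .gold import GoldStandard


@dataclass
class FoldAssignment:
    """Pair -> fold index partition of a gold standard."""

    folds: Dict[Pair, int]
    k: int
    seed: int
    stratified: bool = True

    def held_out(self, fold: int) -> List[Pair]:
        return [p for p, f in self.folds.items() if f == fold]

    def training(self, fold: int) -> List[Pair]:
        return [p for p, f in self.folds.items() if f != fold]


@dataclass
class EvaluationResult:
    """AUC plus a precision-recall curve for one network/gold-standard pair."""

    auc: float
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    n_positives: int
    n_negatives: int
    tissue: str = "GLOBAL"


def assign_folds(
    gs: GoldStandard, k: int, seed: int, stratified: bool = True
) -> FoldAssignment:
    """Randomly partition gold pairs into k folds, stratified per class.

    Within each class, fold sizes differ by at most one.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    folds: Dict[Pair, int] = {}
    if stratified:
        groups: Sequence[Sequence[Pair]] = (sorted(gs.positives), sorted(gs.negatives))
    else:
        groups = (sorted(gs.positives | gs.negatives),)
    for pairs in groups:
        if len(pairs) < k:
            raise ValueError(
                f"class with {len(pairs)} pairs cannot be split into {k} folds"
            )
        idx = rng.permutation(len(pairs))
        for rank, i in enumerate(idx):
            folds[pairs[i]] = rank % k
    return FoldAssignment(folds=folds, k=k, seed=seed, stratified=stratified)


def auc_score(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Probability a random positive outranks a random negative (midrank ties)."""
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([np.asarray(pos_scores, float), np.asarray(neg_scores, float)])
    return float(roc_auc_score(y, s))


def evaluate_scores(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    tissue: str = "GLOBAL",
) -> EvaluationResult:
    """AUC and PR curve from pooled positive/negative scores."""
    if not len(pos_scores) or not len(neg_scores):
        missing = "positive" if not len(pos_scores) else "negative"
        raise ValueError(f"no {missing} scores to evaluate")
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([np.asarray(pos_scores, float), np.asarray(neg_scores, float)])
    prec, rec, thr = precision_recall_curve(y, s)
    # sklearn returns the curve from high threshold to low; store recall ascending
    return EvaluationResult(
        auc=float(roc_auc_score(y, s)),
        precision=prec[::-1],
        recall=rec[::-1],
        thresholds=thr[::-1],
        n_positives=int(len(pos_scores)),
        n_negatives=int(len(neg_scores)),
        tissue=tissue,
    )


def cross_validate(
    datasets: Sequence[EvidenceDataset],
    gs: GoldStandard,
    k: int = 3,
    seed: int = 0,
    n_bins: int = 5,
    alpha: float = 1.0,
    stratified: bool = True,
    regularize: bool = True,
    scheme: Optional[DiscretizationScheme] = None,
) -> EvaluationResult:
    """k-fold pair-level cross-validation of Bayesian integration.

    Each fold is held out in turn; CPTs (and, when ``regularize``,
    MI-regularization weights over continuous datasets) are learned on the
    other folds, and held-out pairs are scored with the resulting posterior.
    Discretization is fit once on the unlabeled score distributions.
    """
    fa = assign_folds(gs, k=k, seed=seed, stratified=stratified)
    if scheme is None:
        scheme = {d.dataset_id: fit_discretization(d, n_bins) for d in datasets}

    held_scores: Dict[Pair, float] = {}
    for fold in range(k):
        train = set(fa.training(fold))
        train_gs = GoldStandard(
            tissue=gs.tissue,
            positives=gs.positives & train,
            negatives=gs.negatives & train,
        )
        weights = None
        if regularize:
            coexpr = [d for d in datasets if d.kind == "continuous"]
            if coexpr:
                weights = regularization_weights(coexpr, scheme).weight
        model = learn_cpts(datasets, train_gs, scheme, alpha=alpha, weights=weights)
        for p in fa.held_out(fold):
            evidence = {
                d.dataset_id: scheme[d.dataset_id].bin_of(d.scores[p])
                for d in datasets if p in d.scores
            }
            held_scores[p] = posterior(model, evidence)

    pos = [held_scores[p] for p in sorted(gs.positives)]
    neg = [held_scores[p] for p in sorted(gs.negatives)]
    return evaluate_scores(pos, neg, tissue=gs.tissue)


def paired_cross_validate(
    datasets: Sequence[EvidenceDataset],
    global_gs: GoldStandard,
    tissue_gs: GoldStandard,
    k: int = 3,
    seed: int = 0,
    n_bins: int = 5,
    alpha: float = 1.0,
    regularize: bool = True,
) -> Tuple[EvaluationResult, EvaluationResult]:
    """Tissue-trained vs globally-trained models on the tissue gold standard.

    Folds are drawn on the tissue gold standard.  Per fold, one model is
    trained on the tissue training folds and one on the global gold
    standard minus the held-out pairs; both score the same held-out tissue
    pairs.  Returns (tissue_result, global_result), so the two AUCs are
    directly comparable — the same evaluation set under two training
    regimes.
    """
    fa = assign_folds(tissue_gs, k=k, seed=seed)
    scheme = {d.dataset_id: fit_discretization(d, n_bins) for d in datasets}
    weights = None
    if regularize:
        coexpr = [d for d in datasets if d.kind == "continuous"]
        if coexpr:
            weights = regularization_weights(coexpr, scheme).weight

    held_t: Dict[Pair, float] = {}
    held_g: Dict[Pair, float] = {}
    for fold in range(k):
        held = fa.held_out(fold)
        held_set = set(held)
        train = set(fa.training(fold))
        tissue_train = GoldStandard(tissue_gs.tissue,
                                    tissue_gs.positives & train,
                                    tissue_gs.negatives & train)
        global_train = GoldStandard(global_gs.tissue,
                                    global_gs.positives - held_set,
                                    global_gs.negatives - held_set)
        m_t = learn_cpts(datasets, tissue_train, scheme, alpha=alpha,
                         weights=weights)
        m_g = learn_cpts(datasets, global_train, scheme, alpha=alpha,
                         weights=weights)
        for p in held:
            evidence = {
                d.dataset_id: scheme[d.dataset_id].bin_of(d.scores[p])
                for d in datasets if p in d.scores
            }
            held_t[p] = posterior(m_t, evidence)
            held_g[p] = posterior(m_g, evidence)

    pos = sorted(tissue_gs.positives)
    neg = sorted(tissue_gs.negatives)
    return (
        evaluate_scores([held_t[p] for p in pos], [held_t[p] for p in neg],
                        tissue=tissue_gs.tissue),
        evaluate_scores([held_g[p] for p in pos], [held_g[p] for p in neg],
                        tissue=global_gs.tissue),
    )


def precision_at_recall(result: EvaluationResult, recall_level: float) -> float:
    """Precision at the smallest threshold reaching at least the given recall."""
    if not (0.0 < recall_level <= 1.0):
        raise ValueError("recall_level must be in (0, 1]")
    reachable = result.recall >= recall_level
    if not reachable.any():
        raise ValueError(f"recall {recall_level} is unreachable")
    # recall stored ascending; the first curve point at or above the target
    # recall corresponds to the highest (most stringent) qualifying threshold
    idx = int(np.argmax(reachable))
    return float(result.precision[idx])
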