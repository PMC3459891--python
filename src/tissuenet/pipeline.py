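"""End-to-end orchestration: integrate, predict, compare.

These functions wire the modules together the way a full run proceeds:
build gold standards from ontology annotations and expression calls, learn
the regularized naive Bayes model per tissue, cross-validate, emit
networks; map phenotypes to tissue networks and rank genes with the bagged
network-feature SVM; compare networks by connectivity change.  The CLI is
a thin wrapper over this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from ._util import log
from .bayes import (DiscretizationScheme, FunctionalNetwork, NaiveBayesModel,
                    fit_discretization, learn_cpts, regularization_weights)
from .bayes import build_network as _build_network
from .compare import DeltaScoreTable, EnrichmentResult, delta_scores, enrich, top_changed
from .evaluation import EvaluationResult, cross_validate
from .evidence import EvidenceDataset, exclude_circular
from .gold import (GLOBAL, AnnotationSet, ExpressionCalls, GoldStandard,
                   Ontology, build_global_gold, build_tissue_gold,
                   propagate_annotations, select_tissues)
from .phenotype import (PhenotypeRanking, bagged_svm, build_features,
                        evaluate_phenotype, map_phenotypes, phenotype_gene_sets)


@dataclass
class IntegrationResult:
    """Networks, models and CV performance for one integration run."""

    networks: Dict[str, FunctionalNetwork]        # tissue tag -> network
    models: Dict[str, NaiveBayesModel]
    cv: Dict[str, EvaluationResult]
    gold: Dict[str, GoldStandard]
    scheme: DiscretizationScheme
    weights: Dict[str, float]


def split_seed(root_seed: int, stage: str) -> int:
    """Derive a stage seed from the root seed, deterministically, < 2^31."""
    import hashlib

    digest = hashlib.sha256(stage.encode()).digest()
    stage_int = int.from_bytes(digest[:4], "big") % (2**31)
    return int(np.random.SeedSequence([root_seed, stage_int])
               .generate_state(1)[0] % (2**31))


def run_integrate(
    datasets: Sequence[EvidenceDataset],
    ontology: Ontology,
    direct_annotations: Mapping[str, Set[str]],
    calls: ExpressionCalls,
    tissues: Optional[Sequence[str]] = None,
    top_n_tissues: Optional[int] = None,
    max_term_size: int = 200,
    n_bins: int = 5,
    alpha: float = 1.0,
    cv_folds: int = 3,
    seed: int = 0,
    for_phenotype_prediction: bool = False,
    min_gold_pairs_per_class: int = 10,
    prior: Optional[float] = None,
) -> IntegrationResult:
    """Build the global network plus one network per selected tissue.

    When ``for_phenotype_prediction`` is set, circularity-sensitive
    (phenotype/disease-derived) evidence is excluded before any model is
    learned.  Tissues with too few gold pairs in either class are skipped
    with a warning.
    """
    if for_phenotype_prediction:
        datasets = exclude_circular(datasets)
    annotations = propagate_annotations(ontology, direct_annotations)
    global_gs = build_global_gold(annotations, ontology, max_term_size)
    if tissues is None:
        tissues = select_tissues(calls, top_n_tissues) if top_n_tissues else calls.tissues()

    scheme = {d.dataset_id: fit_discretization(d, n_bins) for d in datasets}
    coexpr = [d for d in datasets if d.kind == "continuous"]
    weights = regularization_weights(coexpr, scheme).weight if coexpr else {}

    networks: Dict[str, FunctionalNetwork] = {}
    models: Dict[str, NaiveBayesModel] = {}
    cv: Dict[str, EvaluationResult] = {}
    gold: Dict[str, GoldStandard] = {GLOBAL: global_gs}
    for tag in [GLOBAL, *tissues]:
        gs = global_gs if tag == GLOBAL else build_tissue_gold(global_gs, calls, tag)
        if (len(gs.positives) < min_gold_pairs_per_class
                or len(gs.negatives) < min_gold_pairs_per_class):
            log.warning("tissue %s: gold standard too small "
                        "(%d+/%d-); skipped", tag, len(gs.positives),
                        len(gs.negatives))
            continue
        gold[tag] = gs
        model = learn_cpts(datasets, gs, scheme, alpha=alpha, weights=weights,
                           prior=prior)
        models[tag] = model
        # a tissue network spans only the genes called expressed there
        universe = None if tag == GLOBAL else calls.expressed[tag]
        networks[tag] = _build_network(model, datasets, tissue=tag,
                                       gene_universe=universe)
        cv[tag] = cross_validate(datasets, gs, k=cv_folds,
                                 seed=split_seed(seed, f"cv:{tag}"),
                                 n_bins=n_bins, alpha=alpha, scheme=scheme)
    return IntegrationResult(networks=networks, models=models, cv=cv,
                             gold=gold, scheme=scheme, weights=weights)


@dataclass
class PredictionResult:
    """Per-phenotype rankings and evaluation on both candidate networks."""

    phenotype: str
    tissue: Optional[str]                  # mapped tissue, None if unmapped
    rankings: Dict[str, PhenotypeRanking]  # network tag -> ranking
    auc: Dict[str, float]                  # network tag -> out-of-bag AUC


def run_predict(
    integration: IntegrationResult,
    phenotype_ontology: Ontology,
    phenotype_annotations: Mapping[str, Set[str]],
    phenotype_names: Mapping[str, str],
    tissue_names: Mapping[str, str],
    phenotypes: Sequence[str],
    n_bootstraps: int = 100,
    seed: int = 0,
    negative_ratio: Optional[float] = None,
    cost_asymmetry: Optional[float] = None,
    svm_c: float = 1.0,
) -> List[PredictionResult]:
    """Rank genes for each phenotype with the mapped-tissue and global networks."""
    annotations = propagate_annotations(phenotype_ontology, phenotype_annotations)
    cv_auc = {t: r.auc for t, r in integration.cv.items() if t != GLOBAL}
    pmap = map_phenotypes(
        {p: phenotype_names[p] for p in phenotypes},
        {t: tissue_names.get(t, t) for t in integration.networks if t != GLOBAL},
        cv_auc=cv_auc,
    )
    results: List[PredictionResult] = []
    for term in phenotypes:
        tissue = pmap.mapping.get(term)
        if tissue is None:
            log.warning("phenotype %s unmapped; using global network only", term)
        tags = [GLOBAL] if tissue is None else [tissue, GLOBAL]
        rankings: Dict[str, PhenotypeRanking] = {}
        aucs: Dict[str, float] = {}
        for tag in tags:
            net = integration.networks[tag]
            positives, negatives = phenotype_gene_sets(
                annotations, phenotype_ontology, term,
                candidate_genes=net.genes(),
                negative_ratio=negative_ratio,
                seed=split_seed(seed, f"neg:{term}"),
            )
            problem = build_features(net, sorted(positives), sorted(negatives))
            ranking = bagged_svm(problem, n_bootstraps=n_bootstraps,
                                 seed=split_seed(seed, f"bag:{term}:{tag}"),
                                 cost_asymmetry=cost_asymmetry, svm_c=svm_c)
            ranking.phenotype = term
            rankings[tag] = ranking
            aucs[tag] = evaluate_phenotype(ranking, positives, negatives).auc
        results.append(PredictionResult(phenotype=term, tissue=tissue,
                                        rankings=rankings, auc=aucs))
    return results


@dataclass
class ComparisonResult:
    delta: DeltaScoreTable
    top: List[str]
    enrichment: EnrichmentResult


def run_compare(
    network_a: FunctionalNetwork,
    network_b: FunctionalNetwork,
    ontology: Ontology,
    direct_annotations: Mapping[str, Set[str]],
    top_k: int = 100,
    enrich_max_term_size: Optional[int] = None,
) -> ComparisonResult:
    """Connectivity-change ranking of A vs B plus enrichment of top genes.

    The enrichment background is the union of genes present in either
    network; genes without annotations simply never overlap a term.
    ``enrich_max_term_size`` drops near-universal terms from the test.
    """
    annotations = propagate_annotations(ontology, direct_annotations)
    table = delta_scores(network_a, network_b)
    top = top_changed(table, k=top_k)
    background = network_a.genes() | network_b.genes()
    result = enrich(top, annotations, background,
                    max_term_size=enrich_max_term_size)
    return ComparisonResult(delta=table, top=top, enrichment=result)
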