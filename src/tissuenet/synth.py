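"""Synthetic functional-genomics compendia with planted structure.

The generator emulates the statistical structure the integration framework
assumes: genes are organized into co-functional modules; module membership
drives both ontology co-annotation (hence the gold standard) and evidence
scores; some modules are constitutive (active in every tissue) while others
are tissue-restricted — their genes are called expressed, and their
co-functionality is visible to evidence, only in one tissue.

Per continuous dataset, a pair score is drawn from N(mu1, 1) with
probability beta when the pair is co-module and the module is active in the
dataset's tissue context, and from N(0, 1) otherwise; binary datasets use
module-dependent Bernoulli rates.  Redundant datasets are generated as
noisy copies of a partner.  Truth tables record everything planted so that
downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import spearmanr

from ._util import Pair, pair_key
from .evidence import EvidenceDataset
from .gold import AnnotationSet, ExpressionCalls, Ontology

GO_ROOT = "SGO:0000000"
MP_ROOT = "SMP:0000000"


@dataclass
class DatasetSpec:
    """One planted evidence dataset.

    ``beta`` is the probability that a co-module pair's score reflects
    membership rather than noise (informativeness); ``context`` restricts
    the visible modules to one tissue (None = compendium-wide, every module
    active); ``copy_of`` makes the dataset a noisy duplicate of another.
    """

    dataset_id: str
    kind: str = "continuous"
    beta: float = 0.8
    context: Optional[str] = None
    copy_of: Optional[str] = None
    copy_noise: float = 0.1
    effect_size: float = 2.0
    background_rate: float = 0.02  # binary kind: P(edge) for non-module pairs


@dataclass
class SynthConfig:
    """Study conditions for one synthetic compendium.

    Defaults describe a small genome with a dozen co-functional modules,
    a third of them tissue-restricted, observed by an informativeness
    ladder of five compendium-wide continuous datasets.
    """

    seed: int
    n_genes: int = 400
    n_tissues: int = 4
    n_modules: int = 12
    module_size: int = 12
    n_tissue_modules: int = 4
    tissue_expression_fraction: float = 0.5
    n_cross_pairs: int = 4000     # annotated cross-module pairs given evidence
    n_background_pairs: int = 2000  # unannotated pairs given evidence
    n_phenotypes: int = 2
    datasets: Optional[List[DatasetSpec]] = None

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules larger than genome: "
                             f"{self.n_modules} x {self.module_size} > {self.n_genes}")
        if self.n_tissue_modules > self.n_modules:
            raise ValueError("more tissue-restricted modules than modules")
        for p in (self.tissue_expression_fraction,):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.datasets is None:
            betas = np.linspace(0.9, 0.1, 5)
            self.datasets = [
                DatasetSpec(dataset_id=f"ds{i:02d}", beta=float(b))
                for i, b in enumerate(betas)
            ]

    @property
    def gold_max_term_size(self) -> int:
        """Specificity cutoff scaled to the synthetic genome.

        Keeps module terms specific (co-annotation -> positive pair) while
        the root term, covering every annotated gene, stays above the
        cutoff so cross-module pairs become negatives — the same regime
        the 200-gene cutoff produces on a real genome.
        """
        return min(200, 2 * self.module_size)


@dataclass
class Truth:
    """Planted ground truth for recovery scoring."""

    seed: int
    module_of: Dict[str, int]
    modules: Dict[int, List[str]]
    tissue_of_module: Dict[int, Optional[str]]  # None = constitutive
    dataset_order: List[str]  # dataset ids by descending planted beta
    redundant_pairs: List[Tuple[str, str]]
    phenotype_module: Dict[str, int]


@dataclass
class SynthBundle:
    """Everything the pipeline reads, generated from one config."""

    config: SynthConfig
    ontology: Ontology
    direct_annotations: Dict[str, Set[str]]
    calls: ExpressionCalls
    datasets: List[EvidenceDataset]
    phenotype_ontology: Ontology
    phenotype_annotations: Dict[str, Set[str]]
    tissue_names: Dict[str, str]
    phenotype_names: Dict[str, str]
    truth: Truth

    def write(self, outdir: Path) -> None:
        """Write every file format the pipeline reads."""
        from . import io as tio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_obo(outdir / "ontology.obo", self.ontology, "synthetic-go")
        tio.write_annotations(outdir / "annotations.tsv", self.direct_annotations)
        tio.write_expression_calls(outdir / "expression_calls.tsv", self.calls)
        tio.write_obo(outdir / "phenotype_ontology.obo", self.phenotype_ontology,
                      "synthetic-mp")
        tio.write_annotations(outdir / "phenotype_annotations.tsv",
                              self.phenotype_annotations)
        for ds in self.datasets:
            tio.write_evidence(outdir / f"evidence_{ds.dataset_id}.tsv", ds)
        with open(outdir / "truth_modules.tsv", "w") as fh:
            fh.write("# gene_id\tmodule\ttissue\n")
            for g in sorted(self.truth.module_of):
                m = self.truth.module_of[g]
                t = self.truth.tissue_of_module[m] or "GLOBAL"
                fh.write(f"{g}\t{m}\t{t}\n")
        with open(outdir / "truth_datasets.tsv", "w") as fh:
            fh.write("# rank\tdataset_id\n")
            for r, d in enumerate(self.truth.dataset_order):
                fh.write(f"{r}\t{d}\n")


def _module_term(m: int) -> str:
    return f"SGO:{m + 1:07d}"


def _phen_term(k: int) -> str:
    return f"SMP:{k + 1:07d}"


def generate(config: SynthConfig) -> SynthBundle:
    """Generate a full synthetic input bundle; bit-reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    tissues = [f"MA:{t:07d}" for t in range(config.n_tissues)]
    tissue_names = {t: f"synthetic tissue {i:02d}"
                    for i, t in enumerate(tissues)}

    # --- modules: disjoint gene sets; first n_tissue_modules are restricted
    member_pool = rng.permutation(config.n_genes)
    modules: Dict[int, List[str]] = {}
    module_of: Dict[str, int] = {}
    for m in range(config.n_modules):
        chunk = member_pool[m * config.module_size:(m + 1) * config.module_size]
        modules[m] = sorted(genes[i] for i in chunk)
        for g in modules[m]:
            module_of[g] = m
    tissue_of_module: Dict[int, Optional[str]] = {}
    for m in range(config.n_modules):
        if m < config.n_tissue_modules:
            tissue_of_module[m] = tissues[m % config.n_tissues]
        else:
            tissue_of_module[m] = None

    # --- ontology + annotations: one small term per module under one root
    terms = {GO_ROOT} | {_module_term(m) for m in modules}
    parents = {_module_term(m): {GO_ROOT} for m in modules}
    names = {GO_ROOT: "biological process root"}
    names.update({_module_term(m): f"module {m} process" for m in modules})
    ontology = Ontology(terms=terms, parents=parents, names=names)
    direct = {g: {_module_term(module_of[g])} for g in module_of}

    # --- expression calls: constitutive-module genes everywhere;
    #     tissue-module genes only in their tissue; background genes at random
    assay_classes = ["in situ", "RT-PCR", "immunohistochemistry"]
    expressed: Dict[str, Set[str]] = {t: set() for t in tissues}
    for t in tissues:
        mask = rng.random(config.n_genes) < config.tissue_expression_fraction
        for i, g in enumerate(genes):
            m = module_of.get(g)
            if m is None:
                if mask[i]:
                    expressed[t].add(g)
            elif tissue_of_module[m] is None or tissue_of_module[m] == t:
                expressed[t].add(g)
    assay = {(t, g): assay_classes[int(rng.integers(len(assay_classes)))]
             for t in tissues for g in sorted(expressed[t])}
    calls = ExpressionCalls(expressed=expressed, assay_class=assay)

    # --- evidence pair universe
    module_pairs: List[Tuple[Pair, int]] = []
    for m, mg in modules.items():
        for i in range(len(mg)):
            for jj in range(i + 1, len(mg)):
                module_pairs.append((pair_key(mg[i], mg[jj]), m))
    annotated = sorted(module_of)
    cross_pairs: Set[Pair] = set()
    target = min(config.n_cross_pairs,
                 len(annotated) * (len(annotated) - 1) // 2 - len(module_pairs))
    while len(cross_pairs) < target:
        a, b = (str(g) for g in rng.choice(annotated, size=2, replace=False))
        if module_of[a] != module_of[b]:
            cross_pairs.add(pair_key(a, b))
    unannotated = sorted(set(genes) - set(annotated))
    background_pairs: Set[Pair] = set()
    if len(unannotated) >= 2:
        max_bg = len(unannotated) * (len(unannotated) - 1) // 2
        while len(background_pairs) < min(config.n_background_pairs, max_bg):
            a, b = (str(g) for g in rng.choice(unannotated, size=2,
                                               replace=False))
            background_pairs.add(pair_key(a, b))
    noise_pairs = sorted(cross_pairs | background_pairs)

    # --- per-dataset scores
    def module_active(m: int, context: Optional[str]) -> bool:
        restrict = tissue_of_module[m]
        return restrict is None or context is None or restrict == context

    datasets: List[EvidenceDataset] = []
    by_id: Dict[str, EvidenceDataset] = {}
    redundant: List[Tuple[str, str]] = []
    for spec in config.datasets:
        if spec.copy_of is not None:
            src = by_id[spec.copy_of]
            scores = {
                p: (s + rng.normal(0.0, spec.copy_noise)
                    if src.kind == "continuous" else s)
                for p, s in src.scores.items()
            }
            ds = EvidenceDataset(dataset_id=spec.dataset_id, kind=src.kind,
                                 scores=scores,
                                 provenance=f"noisy copy of {spec.copy_of}")
            redundant.append((spec.copy_of, spec.dataset_id))
        elif spec.kind == "continuous":
            scores = {}
            for p, m in module_pairs:
                informative = (module_active(m, spec.context)
                               and rng.random() < spec.beta)
                mu = spec.effect_size if informative else 0.0
                scores[p] = float(rng.normal(mu, 1.0))
            for p in noise_pairs:
                scores[p] = float(rng.normal(0.0, 1.0))
            ds = EvidenceDataset(dataset_id=spec.dataset_id, kind="continuous",
                                 scores=scores,
                                 provenance=f"planted beta={spec.beta}")
        else:
            scores = {}
            for p, m in module_pairs:
                rate = spec.beta if module_active(m, spec.context) \
                    else spec.background_rate
                if rng.random() < rate:
                    scores[p] = 1.0
            for p in noise_pairs:
                if rng.random() < spec.background_rate:
                    scores[p] = 1.0
            ds = EvidenceDataset(dataset_id=spec.dataset_id, kind="binary",
                                 scores=scores,
                                 provenance=f"planted binary beta={spec.beta}")
        datasets.append(ds)
        by_id[ds.dataset_id] = ds

    originals = [s for s in config.datasets if s.copy_of is None]
    dataset_order = [s.dataset_id
                     for s in sorted(originals, key=lambda s: -s.beta)]

    # --- phenotypes: each is one tissue-restricted module (falling back to
    #     constitutive modules when there are not enough restricted ones)
    phen_terms = [_phen_term(k) for k in range(config.n_phenotypes)]
    p_terms = {MP_ROOT} | set(phen_terms)
    p_parents = {t: {MP_ROOT} for t in phen_terms}
    p_names = {MP_ROOT: "phenotype root"}
    phenotype_module: Dict[str, int] = {}
    restricted = [m for m in modules if tissue_of_module[m] is not None]
    order = restricted + [m for m in modules if tissue_of_module[m] is None]
    for k, term in enumerate(phen_terms):
        m = order[k % len(order)]
        phenotype_module[term] = m
        t = tissue_of_module[m]
        tname = tissue_names[t] if t is not None else f"module {m}"
        p_names[term] = f"{tname} dysfunction"
    phenotype_ontology = Ontology(terms=p_terms, parents=p_parents, names=p_names)
    phenotype_annotations: Dict[str, Set[str]] = {}
    for term, m in phenotype_module.items():
        for g in modules[m]:
            phenotype_annotations.setdefault(g, set()).add(term)

    truth = Truth(seed=config.seed, module_of=module_of, modules=modules,
                  tissue_of_module=tissue_of_module,
                  dataset_order=dataset_order, redundant_pairs=redundant,
                  phenotype_module=phenotype_module)
    return SynthBundle(
        config=config, ontology=ontology, direct_annotations=direct,
        calls=calls, datasets=datasets,
        phenotype_ontology=phenotype_ontology,
        phenotype_annotations=phenotype_annotations,
        tissue_names=tissue_names,
        phenotype_names={t: p_names[t] for t in phen_terms},
        truth=truth,
    )


def informativeness_ladder_config(seed: int, n_genes: int = 2000) -> SynthConfig:
    """Five compendium-wide datasets with a planted informativeness ladder.

    The default dataset ladder (beta 0.9 down to 0.1) over a 2000-gene
    genome with forty 15-gene modules; used to check that learned mean
    |LLR| recovers the planted informativeness order.
    """
    return SynthConfig(seed=seed, n_genes=n_genes, n_tissues=4,
                       n_modules=40, module_size=15, n_tissue_modules=0,
                       n_cross_pairs=8000, n_background_pairs=2000)


def redundancy_config(seed: int) -> SynthConfig:
    """One informative dataset plus a near-exact copy of it.

    Mutual-information regularization should assign both close to weight
    1/2: each is almost fully redundant with the other.
    """
    return SynthConfig(
        seed=seed, n_genes=200, n_tissues=2, n_modules=8, module_size=10,
        n_tissue_modules=0, n_cross_pairs=1500, n_background_pairs=500,
        datasets=[DatasetSpec("orig", beta=0.6),
                  DatasetSpec("copy", copy_of="orig", copy_noise=0.01)])


def tissue_recovery_config(seed: int) -> SynthConfig:
    """Mostly tissue-restricted modules observed by per-tissue datasets.

    Nine of twelve modules are restricted to one of three tissues; each
    tissue has a context-limited dataset that sees co-functionality only
    for modules active there, plus one weaker compendium-wide dataset.
    Training on a tissue gold standard should up-weight that tissue's
    context dataset and beat global training on the tissue's own pairs.
    """
    tissues = [f"MA:{t:07d}" for t in range(3)]
    datasets = [DatasetSpec(f"ctx{t}", beta=0.7, context=tissue)
                for t, tissue in enumerate(tissues)]
    datasets.append(DatasetSpec("wide", beta=0.3))
    return SynthConfig(seed=seed, n_genes=300, n_tissues=3, n_modules=12,
                       module_size=10, n_tissue_modules=9,
                       n_cross_pairs=6000, n_background_pairs=0,
                       n_phenotypes=2, datasets=datasets)


def network_comparison_config(seed: int) -> SynthConfig:
    """Tissue-restricted modules inside a larger background genome.

    Like :func:`tissue_recovery_config` but with a 600-gene genome and
    background evidence pairs, so that a top-100 connectivity-change list
    is a small fraction of the network and enrichment of the planted
    tissue-module functions is a meaningful readout.
    """
    tissues = [f"MA:{t:07d}" for t in range(3)]
    datasets = [DatasetSpec(f"ctx{t}", beta=0.7, context=tissue)
                for t, tissue in enumerate(tissues)]
    datasets.append(DatasetSpec("wide", beta=0.3))
    return SynthConfig(seed=seed, n_genes=600, n_tissues=3, n_modules=18,
                       module_size=10, n_tissue_modules=12,
                       n_cross_pairs=6000, n_background_pairs=4000,
                       n_phenotypes=2, datasets=datasets)


@dataclass
class PipelineOutputs:
    """Recovery-relevant outputs of a pipeline run on one bundle."""

    seed: int
    mean_abs_llr: Optional[Dict[str, float]] = None
    tissue_auc: Optional[float] = None
    global_auc: Optional[float] = None
    phenotype_scores: Optional[Dict[str, float]] = None
    phenotype_term: Optional[str] = None


def truth_eval(outputs: PipelineOutputs, truth: Truth) -> Dict[str, float]:
    """Score planted-structure recovery; errors on mismatched seeds."""
    if outputs.seed != truth.seed:
        raise ValueError(
            f"outputs seed {outputs.seed} does not match truth seed {truth.seed}"
        )
    report: Dict[str, float] = {}
    if outputs.mean_abs_llr is not None:
        ids = truth.dataset_order
        planted = np.arange(len(ids))[::-1]  # highest beta = highest rank
        learned = np.array([outputs.mean_abs_llr[d] for d in ids])
        rho = spearmanr(planted, learned).statistic
        report["informativeness_spearman"] = float(rho)
    if outputs.tissue_auc is not None and outputs.global_auc is not None:
        report["tissue_auc"] = outputs.tissue_auc
        report["global_auc"] = outputs.global_auc
        report["tissue_vs_global_gap"] = outputs.tissue_auc - outputs.global_auc
    if outputs.phenotype_scores is not None and outputs.phenotype_term is not None:
        from .evaluation import auc_score

        planted_genes = set(truth.modules[truth.phenotype_module[outputs.phenotype_term]])
        pos = [s for g, s in outputs.phenotype_scores.items() if g in planted_genes]
        neg = [s for g, s in outputs.phenotype_scores.items() if g not in planted_genes]
        report["phenotype_auc"] = auc_score(pos, neg)
    return report


def mean_abs_llr(model, datasets: Sequence[EvidenceDataset]) -> Dict[str, float]:
    """Mean |log-likelihood ratio| of each dataset's evidence over its pairs.

    A model-derived informativeness summary: the average absolute additive
    contribution a dataset makes to the posterior log-odds, taken over the
    dataset's observed score distribution.
    """
    out: Dict[str, float] = {}
    for ds in datasets:
        spec = model.scheme[ds.dataset_id]
        vals = np.array(list(ds.scores.values()))
        bins = spec.bins_of(vals)
        table = model.cpt[ds.dataset_id]
        llr = np.log(table[:, 0] / table[:, 1])
        out[ds.dataset_id] = float(np.abs(llr[bins]).mean())
    return out
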