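"""Regularized naive Bayes integration of heterogeneous pairwise evidence.

The posterior probability that a gene pair (i, j) is functionally related
(FR = 1) given its evidence across k datasets is, in log-odds form,

    logit P(FR=1 | E) = logit P(FR=1) + sum_k w_k * ln[ P(E_k|FR=1) / P(E_k|FR=0) ]

where the per-dataset likelihoods come from binned conditional probability
tables (CPTs) learned against a gold standard with Laplace smoothing, and
w_k is a mutual-information regularization weight.  Co-expression datasets
overlap heavily in information; for each such dataset k the ratio

    r_k = sum_{l != k} I(k, l) / H(k)

of its summed mutual information with the other co-expression datasets to
its own entropy measures that redundancy, and w_k = 1 / (1 + r_k) shrinks
its log-likelihood-ratio contribution accordingly (w = 1 when a dataset is
independent of all others; w -> 1/2 for a dataset fully duplicated once).
Datasets outside the regularized group keep w = 1.  Evidence absent for a
pair is marginalized out by omission from the sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from ._util import Pair, log, pair_key
from .evidence import EvidenceDataset
from .gold import GLOBAL, GoldStandard

MISSING = -1  # reserved bin index for absent evidence (used only behind a flag)


@dataclass
class BinSpec:
    """Discretization of one dataset's scores into ordered bins.

    Continuous datasets use equal-frequency edges: score s falls in bin
    ``searchsorted(edges, s)``; ``n_bins = len(edges) + 1``.  Binary
    datasets pass through with bins {0, 1} and no edges.
    """

    dataset_id: str
    kind: str
    edges: np.ndarray  # interior edges, strictly increasing; empty for binary

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size and not (np.diff(e) > 0).all():
            raise ValueError("bin edges must be strictly increasing")
        self.edges = e

    @property
    def n_bins(self) -> int:
        return 2 if self.kind == "binary" else len(self.edges) + 1

    def bin_of(self, score: float) -> int:
        if self.kind == "binary":
            return int(score)
        return int(np.searchsorted(self.edges, score, side="right"))

    def bins_of(self, scores: np.ndarray) -> np.ndarray:
        if self.kind == "binary":
            return scores.astype(int)
        return np.searchsorted(self.edges, scores, side="right").astype(int)


DiscretizationScheme = Dict[str, BinSpec]


def fit_discretization(ds: EvidenceDataset, n_bins: int = 5) -> BinSpec:
    """Equal-frequency bin edges over a dataset's observed scores.

    If the dataset has fewer distinct values than requested bins the bin
    count is reduced (a constant dataset collapses to a single bin and
    contributes zero log-likelihood ratio after smoothing).
    """
    if ds.kind == "binary":
        return BinSpec(ds.dataset_id, "binary", np.array([]))
    values = np.array(sorted(ds.scores.values()), dtype=float)
    distinct = np.unique(values)
    k = min(n_bins, len(distinct))
    if k < n_bins:
        log.info("dataset %s: only %d distinct scores; using %d bin(s)",
                 ds.dataset_id, len(distinct), k)
    if k <= 1:
        return BinSpec(ds.dataset_id, "continuous", np.array([]))
    qs = np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
    edges = np.unique(qs)
    return BinSpec(ds.dataset_id, "continuous", edges)


@dataclass
class NaiveBayesModel:
    """Prior, per-dataset binned CPTs, and regularization weights.

    ``cpt[k]`` is an (n_bins, 2) array: column 0 = P(bin | FR=1), column 1 =
    P(bin | FR=0), each column summing to 1 after Laplace smoothing with
    pseudo-count ``alpha``.
    """

    prior: float
    scheme: DiscretizationScheme
    cpt: Dict[str, np.ndarray]
    weight: Dict[str, float]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError(f"prior must be in (0, 1), got {self.prior}")
        for k, table in self.cpt.items():
            if not np.allclose(table.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError(f"CPT columns of {k!r} do not sum to 1")
            if (table <= 0).any():
                raise ValueError(f"CPT of {k!r} has non-positive entries")
        for k, w in self.weight.items():
            if not (0.0 < w <= 1.0):
                raise ValueError(f"weight of {k!r} out of (0, 1]: {w}")

    def llr(self, dataset_id: str, bin_idx: int) -> float:
        """Unweighted log-likelihood ratio of one evidence bin."""
        table = self.cpt[dataset_id]
        return math.log(table[bin_idx, 0] / table[bin_idx, 1])


@dataclass
class RegularizationReport:
    """Per-dataset entropy, summed mutual information, ratio, and weight."""

    entropy: Dict[str, float]
    mi_sum: Dict[str, float]
    ratio: Dict[str, float]
    weight: Dict[str, float]
    pairwise_mi: Dict[Tuple[str, str], float] = field(default_factory=dict)


@dataclass
class FunctionalNetwork:
    """Gene pair -> posterior probability of functional relationship."""

    tissue: str
    prior: float
    scores: Dict[Pair, float]

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must be in (0, 1)")
        for p, v in self.scores.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"posterior out of [0, 1] at {p}: {v}")

    def get(self, a: str, b: str, default: Optional[float] = None) -> Optional[float]:
        return self.scores.get(pair_key(a, b), default)

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.scores:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.scores)


def learn_cpts(
    datasets: Sequence[EvidenceDataset],
    gs: GoldStandard,
    scheme: DiscretizationScheme,
    alpha: float = 1.0,
    prior: Optional[float] = None,
    weights: Optional[Mapping[str, float]] = None,
) -> NaiveBayesModel:
    """Learn per-dataset CPTs against a gold standard.

    For dataset k, bin b and class c the smoothed likelihood is
    (count(b, c) + alpha) / (count(., c) + alpha * n_bins); gold pairs with
    no score in k are excluded from k's counts.  The prior defaults to the
    gold-standard class balance |P| / (|P| + |N|).
    """
    if not gs.positives or not gs.negatives:
        empty = "positives" if not gs.positives else "negatives"
        raise ValueError(f"gold standard has no {empty}")
    cpt: Dict[str, np.ndarray] = {}
    for ds in datasets:
        spec = scheme[ds.dataset_id]
        counts = np.zeros((spec.n_bins, 2), dtype=float)
        for col, pairs in enumerate((gs.positives, gs.negatives)):
            for p in pairs:
                s = ds.scores.get(p)
                if s is not None:
                    counts[spec.bin_of(s), col] += 1
        table = (counts + alpha) / (counts.sum(axis=0) + alpha * spec.n_bins)
        cpt[ds.dataset_id] = table
    if prior is None:
        prior = len(gs.positives) / (len(gs.positives) + len(gs.negatives))
    w = {ds.dataset_id: 1.0 for ds in datasets}
    if weights:
        w.update({k: v for k, v in weights.items() if k in w})
    return NaiveBayesModel(prior=prior, scheme=dict(scheme), cpt=cpt,
                           weight=w, alpha=alpha)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy (natural log) of a probability vector."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information (nats) of an empirical joint count/probability table."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total <= 0:
        return 0.0
    pxy = joint / total
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float((pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])).sum())


def regularization_weights(
    coexpr_datasets: Sequence[EvidenceDataset],
    scheme: DiscretizationScheme,
) -> RegularizationReport:
    """Mutual-information regularization weights for co-expression datasets.

    MI between two datasets is estimated from the empirical joint bin
    distribution over the pairs present in both; entropy from each
    dataset's own bin distribution.  A dataset with zero entropy (single
    bin) has no content to regularize and keeps w = 1.
    """
    if not coexpr_datasets:
        raise ValueError("need at least one co-expression dataset")
    ids = [d.dataset_id for d in coexpr_datasets]
    binned: Dict[str, Dict[Pair, int]] = {}
    for ds in coexpr_datasets:
        spec = scheme[ds.dataset_id]
        pairs = list(ds.scores)
        bins = spec.bins_of(np.array([ds.scores[p] for p in pairs]))
        binned[ds.dataset_id] = dict(zip(pairs, bins.tolist()))

    entropy: Dict[str, float] = {}
    for ds in coexpr_datasets:
        spec = scheme[ds.dataset_id]
        counts = np.bincount(list(binned[ds.dataset_id].values()),
                             minlength=spec.n_bins).astype(float)
        entropy[ds.dataset_id] = _entropy(counts / counts.sum())

    pairwise: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = binned[a].keys() & binned[b].keys()
            if not shared:
                pairwise[(a, b)] = 0.0
                continue
            na = scheme[a].n_bins
            nb = scheme[b].n_bins
            joint = np.zeros((na, nb))
            for p in shared:
                joint[binned[a][p], binned[b][p]] += 1
            pairwise[(a, b)] = mutual_information(joint)

    mi_sum = {k: 0.0 for k in ids}
    for (a, b), mi in pairwise.items():
        mi_sum[a] += mi
        mi_sum[b] += mi

    ratio: Dict[str, float] = {}
    weight: Dict[str, float] = {}
    for k in ids:
        if entropy[k] <= 0:
            warnings.warn(f"dataset {k!r} has zero entropy; weight left at 1")
            ratio[k] = 0.0
            weight[k] = 1.0
        else:
            ratio[k] = mi_sum[k] / entropy[k]
            weight[k] = 1.0 / (1.0 + ratio[k])
    return RegularizationReport(entropy=entropy, mi_sum=mi_sum, ratio=ratio,
                                weight=weight, pairwise_mi=pairwise)


def posterior(model: NaiveBayesModel, evidence: Mapping[str, int]) -> float:
    """Posterior P(FR=1 | evidence) for one pair.

    ``evidence`` maps dataset id -> bin index; datasets not supplied are
    marginalized out (their factors drop from the product).  With no
    evidence at all the posterior equals the prior.
    """
    logit = math.log(model.prior / (1.0 - model.prior))
    for k, b in evidence.items():
        if k not in model.cpt:
            raise KeyError(f"unknown dataset id: {k!r}")
        logit += model.weight[k] * model.llr(k, b)
    return 1.0 / (1.0 + math.exp(-logit))


def build_network(
    model: NaiveBayesModel,
    datasets: Sequence[EvidenceDataset],
    gene_universe: Optional[Iterable[str]] = None,
    tissue: str = GLOBAL,
    include_no_evidence: bool = False,
) -> FunctionalNetwork:
    """Score every unordered pair with at least one observed evidence value.

    ``gene_universe`` restricts scoring to pairs within the given genes
    (default: every gene seen in any dataset).  Pairs with no evidence are
    omitted unless ``include_no_evidence``, in which case universe pairs
    with no evidence are set to the prior.
    """
    universe = set(gene_universe) if gene_universe is not None else None
    if universe is not None and len(universe) < 2:
        raise ValueError("gene universe must contain at least 2 genes")

    # per-dataset vectorized binning, then accumulate weighted LLRs per pair
    prior_logit = math.log(model.prior / (1.0 - model.prior))
    logits: Dict[Pair, float] = {}
    for ds in datasets:
        spec = model.scheme[ds.dataset_id]
        table = model.cpt[ds.dataset_id]
        w = model.weight[ds.dataset_id]
        llr_by_bin = w * np.log(table[:, 0] / table[:, 1])
        pairs = list(ds.scores)
        bins = spec.bins_of(np.array([ds.scores[p] for p in pairs]))
        for p, b in zip(pairs, bins.tolist()):
            if universe is not None and (p[0] not in universe or p[1] not in universe):
                continue
            logits[p] = logits.get(p, prior_logit) + llr_by_bin[b]

    scores = {p: 1.0 / (1.0 + math.exp(-v)) for p, v in logits.items()}
    if include_no_evidence and universe is not None:
        ordered = sorted(universe)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                scores.setdefault((a, b), model.prior)
    return FunctionalNetwork(tissue=tissue, prior=model.prior, scores=scores)
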