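"""Cross-network comparison: per-gene connectivity change and enrichment.

For networks X and Y with priors P_x and P_y, a gene's change score is the
summed absolute difference of its prior-normalized connection weights,

    D(i) = sum_n | X_in / P_x  -  Y_in / P_y |

over all partners n present in either network.  An edge absent from one
network is imputed at that network's prior (fold change 1), so coverage
differences alone do not register as change.  The top changed genes are
then tested for ontology-term enrichment with a one-sided hypergeometric
test and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._util import Pair, pair_key
from .bayes import FunctionalNetwork
from .gold import AnnotationSet


@dataclass
class DeltaScoreTable:
    """Per-gene connectivity-change scores between two networks."""

    scores: Dict[str, float]
    network_x: str
    network_y: str
    prior_x: float
    prior_y: float

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.scores.items() if d < 0}
        if bad:
            raise ValueError(f"negative delta scores: {bad}")


@dataclass
class EnrichmentResult:
    """Per-term overlap counts and hypergeometric p / BH q values."""

    terms: List[str]
    overlap: Dict[str, int]
    expected: Dict[str, float]
    p: Dict[str, float]
    q: Dict[str, float]
    term_names: Dict[str, str] = field(default_factory=dict)


def delta_scores(
    x: FunctionalNetwork,
    y: FunctionalNetwork,
    log_ratio: bool = False,
) -> DeltaScoreTable:
    """Per-gene summed |fold-change-over-prior difference| between networks.

    ``log_ratio`` switches to |ln(X_in/P_x) - ln(Y_in/P_y)| per edge, an
    alternative reading of "fold change"; the linear ratio is the default.
    """
    if x.prior <= 0 or y.prior <= 0:
        raise ValueError("network priors must be positive")
    partners: Dict[str, Set[str]] = {}
    edges: Set[Pair] = set(x.scores) | set(y.scores)
    for a, b in edges:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    def ratio(net: FunctionalNetwork, p: Pair) -> float:
        s = net.scores.get(p)
        return 1.0 if s is None else s / net.prior

    out: Dict[str, float] = {}
    for g, ns in partners.items():
        total = 0.0
        for n in ns:
            p = pair_key(g, n)
            rx, ry = ratio(x, p), ratio(y, p)
            if log_ratio:
                if rx <= 0 or ry <= 0:
                    raise ValueError(f"zero edge ratio at {p}; log form undefined")
                total += abs(math.log(rx) - math.log(ry))
            else:
                total += abs(rx - ry)
        out[g] = total
    return DeltaScoreTable(scores=out, network_x=x.tissue, network_y=y.tissue,
                           prior_x=x.prior, prior_y=y.prior)


def top_changed(table: DeltaScoreTable, k: int = 100) -> List[str]:
    """The k genes with the largest change scores, ties lexicographic."""
    if not table.scores:
        raise ValueError("empty delta-score table")
    ranked = sorted(table.scores, key=lambda g: (-table.scores[g], g))
    if k > len(ranked):
        warnings.warn(f"requested top {k} of {len(ranked)} genes; returning all")
        return ranked
    return ranked[:k]


def enrich(
    genes: Iterable[str],
    annotations: AnnotationSet,
    background: Iterable[str],
    min_term_size: int = 1,
    max_term_size: Optional[int] = None,
) -> EnrichmentResult:
    """One-sided hypergeometric term enrichment of a gene set.

    Tests every term annotated (post-propagation) to at least one gene of
    the query set; p = P(overlap >= observed) under sampling |set| genes
    from the background without replacement.  Benjamini-Hochberg adjusts
    across the tested terms.  ``min_term_size`` / ``max_term_size`` bound
    the background annotation count of tested terms, the usual guard
    against trivially enriched near-universal terms (ontology roots).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    query = set(genes)
    stray = query - bg
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")

    term_genes: Dict[str, Set[str]] = {}
    for g in bg:
        for t in annotations.propagated.get(g, ()):
            term_genes.setdefault(t, set()).add(g)

    M, N = len(bg), len(query)
    terms: List[str] = []
    overlap: Dict[str, int] = {}
    expected: Dict[str, float] = {}
    pvals: List[float] = []
    for t in sorted(term_genes):
        K = len(term_genes[t])
        if K < min_term_size or (max_term_size is not None and K > max_term_size):
            continue
        k_obs = len(term_genes[t] & query)
        if k_obs == 0:
            continue
        terms.append(t)
        overlap[t] = k_obs
        expected[t] = K * N / M
        pvals.append(float(hypergeom.sf(k_obs - 1, M, K, N)))
    if terms:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = np.array([])
    return EnrichmentResult(
        terms=terms,
        overlap=overlap,
        expected=expected,
        p=dict(zip(terms, pvals)),
        q=dict(zip(terms, qvals.tolist())),
    )


def local_neighborhood(
    network: FunctionalNetwork,
    query: Sequence[str],
    k: int = 18,
    min_weight: Optional[float] = None,
) -> Dict[Pair, float]:
    """Edges of the top-k partners of a query gene set.

    Partners are ranked by their maximum connection weight to any query
    gene (optionally thresholded at ``min_weight``); the returned edge set
    contains query-partner and query-internal edges, threshold applied.
    With k = 0 only query-internal edges are returned.
    """
    net_genes = network.genes()
    for g in query:
        if g not in net_genes:
            raise KeyError(f"query gene absent from network: {g!r}")
    qset = set(query)

    best: Dict[str, float] = {}
    for (a, b), w in network.scores.items():
        if a in qset and b not in qset:
            best[b] = max(best.get(b, float("-inf")), w)
        elif b in qset and a not in qset:
            best[a] = max(best.get(a, float("-inf")), w)
    if min_weight is not None:
        best = {g: w for g, w in best.items() if w > min_weight}
    chosen = sorted(best, key=lambda g: (-best[g], g))[:k]
    keep = qset | set(chosen)

    edges: Dict[Pair, float] = {}
    for (a, b), w in network.scores.items():
        if a in keep and b in keep and (a in qset or b in qset):
            if min_weight is not None and w <= min_weight:
                continue
            edges[(a, b)] = w
    return edges
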