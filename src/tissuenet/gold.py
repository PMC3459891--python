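"""Ontologies, annotation propagation, and functional gold standards.

A gold standard is a labeled set of gene pairs used to train and evaluate
Bayesian data integration.  Positive pairs are co-annotated to a *specific*
biological-process term — one with fewer than ``max_term_size`` annotated
genes after propagation — and negative pairs are those in which both genes
carry at least one specific annotation but share none.  Tissue-specific gold
standards restrict the global one to pairs whose genes are both called
expressed in the tissue by curated, low-throughput assays.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

from ._util import Pair, log, pair_key

GLOBAL = "GLOBAL"
#: tissue tag of a gold standard or network built without tissue restriction


@dataclass
class Ontology:
    """A DAG of terms connected by is_a / part_of edges.

    ``parents[t]`` holds the direct parents of ``t``; ancestors are reached
    by transitive closure.  The graph must be acyclic and closed (every
    referenced parent is itself a term).
    """

    terms: Set[str]
    parents: Dict[str, Set[str]]
    names: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, ps in self.parents.items():
            if t not in self.terms:
                raise ValueError(f"parent map references unknown term {t!r}")
            missing = ps - self.terms
            if missing:
                raise ValueError(
                    f"term {t!r} has unknown parent(s): {sorted(missing)}"
                )
        self._check_acyclic()
        self._anc_cache: Dict[str, FrozenSet[str]] = {}

    def _check_acyclic(self) -> None:
        state: Dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str, stack: List[str]) -> None:
            if state.get(t) == 1:
                return
            if state.get(t) == 0:
                raise ValueError(f"cycle in ontology involving {t!r}")
            state[t] = 0
            for p in self.parents.get(t, ()):
                visit(p, stack + [t])
            state[t] = 1

        for t in self.terms:
            visit(t, [])

    def ancestors(self, term: str) -> FrozenSet[str]:
        """All ancestors of ``term`` (excluding itself), memoized."""
        if term not in self.terms:
            raise KeyError(f"unknown term: {term!r}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out: Set[str] = set()
        for p in self.parents.get(term, ()):
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def descendants(self, term: str) -> FrozenSet[str]:
        """All descendants of ``term`` (excluding itself)."""
        if term not in self.terms:
            raise KeyError(f"unknown term: {term!r}")
        children: Dict[str, Set[str]] = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        out: Set[str] = set()
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for c in children[t]:
                if c not in out:
                    out.add(c)
                    frontier.append(c)
        return frozenset(out)


@dataclass
class AnnotationSet:
    """Gene → term annotations, direct and hierarchy-propagated."""

    direct: Dict[str, Set[str]]
    propagated: Dict[str, Set[str]]

    def genes(self) -> Set[str]:
        return set(self.propagated)


@dataclass
class ExpressionCalls:
    """Curated tissue → expressed-gene presence calls.

    ``assay_class`` records the evidence class of each (tissue, gene) call,
    e.g. "in situ" or "RT-PCR"; filtering on it is optional.
    """

    expressed: Dict[str, Set[str]]
    assay_class: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, gs in self.expressed.items() if not gs]
        if empty:
            raise ValueError(f"tissues with empty gene sets: {sorted(empty)}")

    def tissues(self) -> List[str]:
        return sorted(self.expressed)

    def filter_classes(self, accepted: Set[str]) -> "ExpressionCalls":
        """Keep only calls whose assay class is in ``accepted``."""
        expressed: Dict[str, Set[str]] = {}
        assay: Dict[Tuple[str, str], str] = {}
        for (t, g), cls in self.assay_class.items():
            if cls in accepted:
                expressed.setdefault(t, set()).add(g)
                assay[(t, g)] = cls
        return ExpressionCalls(expressed=expressed, assay_class=assay)


@dataclass
class GoldStandard:
    """Labeled unordered gene pairs, optionally scoped to one tissue."""

    tissue: str
    positives: Set[Pair]
    negatives: Set[Pair]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"pairs labeled both ways: {sorted(overlap)[:5]}")
        for p in itertools.chain(self.positives, self.negatives):
            if p[0] >= p[1]:
                raise ValueError(f"non-canonical or self pair: {p}")

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in itertools.chain(self.positives, self.negatives):
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def propagate_annotations(
    ontology: Ontology, direct: Mapping[str, Set[str]]
) -> AnnotationSet:
    """Propagate each gene's annotations to all ancestor terms.

    Idempotent: propagating an already-propagated annotation set is a no-op,
    because ancestor sets are closed under the parent relation.

    Raises ``KeyError`` naming the first term not present in the ontology.
    """
    propagated: Dict[str, Set[str]] = {}
    for gene, terms in direct.items():
        unknown = set(terms) - ontology.terms
        if unknown:
            raise KeyError(
                f"gene {gene!r} annotated to unknown term {sorted(unknown)[0]!r}"
            )
        full: Set[str] = set(terms)
        for t in terms:
            full |= ontology.ancestors(t)
        propagated[gene] = full
    return AnnotationSet(
        direct={g: set(ts) for g, ts in direct.items()}, propagated=propagated
    )


def term_sizes(annotations: AnnotationSet) -> Dict[str, int]:
    """Number of genes annotated (post-propagation) to each term."""
    sizes: Dict[str, int] = {}
    for terms in annotations.propagated.values():
        for t in terms:
            sizes[t] = sizes.get(t, 0) + 1
    return sizes


def build_global_gold(
    annotations: AnnotationSet,
    ontology: Optional[Ontology] = None,
    max_term_size: int = 200,
) -> GoldStandard:
    """Construct the global gold standard from propagated annotations.

    Positives: pairs co-annotated to at least one term with fewer than
    ``max_term_size`` annotated genes.  Negatives: pairs where both genes
    hold at least one such specific term but share none.  Term sizes are
    counted on propagated annotations, so a gene annotated only to a child
    contributes to every ancestor's size.
    """
    if max_term_size < 1:
        raise ValueError("max_term_size must be >= 1")
    if not annotations.propagated:
        warnings.warn("empty annotation set; returning empty gold standard")
        return GoldStandard(GLOBAL, set(), set())

    sizes = term_sizes(annotations)
    specific = {t for t, n in sizes.items() if n < max_term_size}
    # genes carrying >=1 specific term are eligible for labels at all
    spec_terms: Dict[str, FrozenSet[str]] = {}
    for g, terms in annotations.propagated.items():
        st = frozenset(terms & specific)
        if st:
            spec_terms[g] = st

    positives: Set[Pair] = set()
    negatives: Set[Pair] = set()
    eligible = sorted(spec_terms)
    for i, a in enumerate(eligible):
        ta = spec_terms[a]
        for b in eligible[i + 1:]:
            if ta & spec_terms[b]:
                positives.add((a, b))
            else:
                negatives.add((a, b))
    return GoldStandard(GLOBAL, positives, negatives)


def build_tissue_gold(
    global_gs: GoldStandard, calls: ExpressionCalls, tissue: str
) -> GoldStandard:
    """Restrict a global gold standard to pairs expressed in one tissue."""
    if tissue not in calls.expressed:
        raise KeyError(f"tissue not present in expression calls: {tissue!r}")
    genes = calls.expressed[tissue]
    keep = lambda p: p[0] in genes and p[1] in genes
    return GoldStandard(
        tissue=tissue,
        positives={p for p in global_gs.positives if keep(p)},
        negatives={p for p in global_gs.negatives if keep(p)},
    )


def select_tissues(calls: ExpressionCalls, n: int) -> List[str]:
    """The ``n`` tissues with the largest expressed-gene sets.

    Ranked by descending set size; ties broken lexicographically by tissue
    identifier.  If ``n`` exceeds the tissue count, all tissues are returned
    with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(calls.expressed, key=lambda t: (-len(calls.expressed[t]), t))
    if n > len(ranked):
        warnings.warn(
            f"requested {n} tissues but only {len(ranked)} available; returning all"
        )
        return ranked
    return ranked[:n]
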