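"""Per-dataset pairwise evidence: co-expression, interactions, ortholog
transfer, and phenotype/disease co-occurrence similarity.

Every raw data source is reduced to a map from unordered gene pairs to a
similarity score S(i, j) — continuous for co-expression and transferred
network scores, binary for grouped interaction evidence.  These maps are the
per-dataset evidence E_k consumed by the naive Bayes integrator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from ._util import Pair, log, pair_key

FISHER_Z_CLAMP = 1e-6  # keeps atanh finite at |rho| = 1
GROUPED_SMALL = "grouped_small_types"


@dataclass
class EvidenceDataset:
    """One preprocessed data source: unordered gene pair -> score.

    ``kind`` is "continuous" or "binary"; binary scores are 0/1 presence
    flags.  ``circularity_sensitive`` marks phenotype/disease-derived
    evidence that must be dropped when the network will be used to predict
    phenotype genes.
    """

    dataset_id: str
    kind: str
    scores: Dict[Pair, float]
    provenance: str = ""
    circularity_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown evidence kind: {self.kind!r}")
        for (a, b), v in self.scores.items():
            if a >= b:
                raise ValueError(f"non-canonical or self pair: {(a, b)}")
            if self.kind == "binary" and v not in (0.0, 1.0):
                raise ValueError(f"binary dataset with non-0/1 score {v} at {(a, b)}")

    def get(self, a: str, b: str) -> Optional[float]:
        return self.scores.get(pair_key(a, b))

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.scores:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with NaN as missing."""

    genes: List[str]
    samples: List[str]
    values: np.ndarray  # shape (n_genes, n_samples), float, NaN = missing

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample lists")


@dataclass
class PhenotypeMatrix:
    """Binary gene x phenotype incidence: a[i, k] = 1 iff gene i has phenotype k."""

    genes: List[str]
    phenotypes: List[str]
    a: np.ndarray  # (n_genes, n_phenotypes) of {0, 1}

    def __post_init__(self) -> None:
        if self.a.shape != (len(self.genes), len(self.phenotypes)):
            raise ValueError("incidence shape mismatch")
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")

    @property
    def counts(self) -> np.ndarray:
        """N_k: number of genes annotated to each phenotype (column sums)."""
        return self.a.sum(axis=0)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)


@dataclass
class OrthologMap:
    """Source gene -> set of target-species genes (non-empty sets only)."""

    mapping: Dict[str, Set[str]]

    def __post_init__(self) -> None:
        empty = [g for g, ts in self.mapping.items() if not ts]
        if empty:
            raise ValueError(f"empty ortholog target sets for: {sorted(empty)}")


def coexpression_scores(
    m: ExpressionMatrix,
    min_samples: int = 3,
    dataset_id: str = "coexpression",
) -> EvidenceDataset:
    """Pearson correlation -> Fisher z -> standardize to ~N(0, 1).

    For each gene pair the correlation is computed over samples where both
    genes are observed; pairs with fewer than ``min_samples`` joint
    observations, or involving a zero-variance profile, are absent from the
    result.  The z-scores are standardized by the mean and standard
    deviation over all emitted pairs, so the emitted distribution has mean 0
    and unit variance by construction.
    """
    if len(m.samples) < min_samples:
        raise ValueError(
            f"matrix has {len(m.samples)} samples; need >= {min_samples}"
        )
    vals = np.asarray(m.values, dtype=float)
    n_genes = len(m.genes)
    obs = ~np.isnan(vals)

    pairs: List[Pair] = []
    zs: List[float] = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            joint = obs[i] & obs[j]
            if joint.sum() < min_samples:
                continue
            xi, xj = vals[i, joint], vals[j, joint]
            if xi.std() == 0 or xj.std() == 0:
                log.debug("zero-variance profile; skipping pair (%s, %s)",
                          m.genes[i], m.genes[j])
                continue
            rho = float(np.corrcoef(xi, xj)[0, 1])
            rho = min(max(rho, -1.0 + FISHER_Z_CLAMP), 1.0 - FISHER_Z_CLAMP)
            pairs.append(pair_key(m.genes[i], m.genes[j]))
            zs.append(math.atanh(rho))

    z = np.array(zs, dtype=float)
    if len(z) > 1 and z.std() > 0:
        z = (z - z.mean()) / z.std()
    elif len(z):
        z = z - z.mean()
    return EvidenceDataset(
        dataset_id=dataset_id,
        kind="continuous",
        scores=dict(zip(pairs, z.tolist())),
        provenance=f"Pearson + Fisher z over {len(m.samples)} samples",
    )


def group_interactions(
    edges: Iterable[Tuple[str, str, str]],
    min_group: int = 1000,
) -> List[EvidenceDataset]:
    """Split interaction evidence into one binary dataset per experiment type.

    Types with fewer than ``min_group`` distinct pairs are merged into a
    single dataset named "grouped_small_types" so that each dataset carries
    enough examples to estimate its conditional probability tables.
    Duplicate edges within a type collapse to one binary entry.
    """
    by_type: Dict[str, Set[Pair]] = {}
    for a, b, etype in edges:
        if not etype:
            raise ValueError("empty experiment type")
        if a == b:
            continue
        by_type.setdefault(etype, set()).add(pair_key(a, b))

    out: List[EvidenceDataset] = []
    merged: Dict[Pair, float] = {}
    merged_types: List[str] = []
    for etype in sorted(by_type):
        pairs = by_type[etype]
        if len(pairs) >= min_group:
            out.append(EvidenceDataset(
                dataset_id=f"interaction:{etype}",
                kind="binary",
                scores={p: 1.0 for p in pairs},
                provenance=f"experiment type {etype}",
            ))
        else:
            merged_types.append(etype)
            for p in pairs:
                merged[p] = 1.0
    if merged:
        out.append(EvidenceDataset(
            dataset_id=GROUPED_SMALL,
            kind="binary",
            scores=merged,
            provenance="merged small experiment types: " + ",".join(merged_types),
        ))
    return out


def transfer_ortholog_scores(
    src: EvidenceDataset, omap: OrthologMap, dataset_id: Optional[str] = None
) -> EvidenceDataset:
    """Map a source-species evidence dataset onto target genes.

    Each target pair receives the arithmetic mean of every source score that
    maps onto it; pairs whose genes collapse onto a single target gene are
    dropped (no self-pairs).
    """
    sums: Dict[Pair, float] = {}
    counts: Dict[Pair, int] = {}
    for (i, j), s in src.scores.items():
        for x in omap.mapping.get(i, ()):
            for y in omap.mapping.get(j, ()):
                if x == y:
                    continue
                p = pair_key(x, y)
                sums[p] = sums.get(p, 0.0) + s
                counts[p] = counts.get(p, 0) + 1
    return EvidenceDataset(
        dataset_id=dataset_id or f"{src.dataset_id}:ortholog_transfer",
        kind=src.kind,
        scores={p: sums[p] / counts[p] for p in sums},
        provenance=f"ortholog transfer of {src.dataset_id}",
        circularity_sensitive=src.circularity_sensitive,
    )


def phenotype_similarity(
    pm: PhenotypeMatrix,
    normalize_by_total: bool = False,
    dataset_id: str = "phenotype_similarity",
) -> EvidenceDataset:
    """Weighted phenotype/disease co-occurrence similarity.

    S(i, j) = sum_k a_ik * a_jk / N_k, so that sharing a rarely annotated
    phenotype contributes more than sharing a broadly annotated one.  Only
    pairs with S > 0 are stored.  ``normalize_by_total`` divides by the
    total number of phenotypes n (an optional variant; off by default).

    The result is tagged circularity-sensitive: it must never feed a network
    later used for phenotype gene prediction.
    """
    N = pm.counts.astype(float)
    if (N < 1).any():
        bad = [pm.phenotypes[k] for k in np.nonzero(N < 1)[0]]
        raise ValueError(f"phenotypes with no annotated genes: {bad}")
    weighted = pm.a / N  # a_ik / N_k, column-wise
    sim = weighted @ pm.a.T  # sim[i, j] = sum_k a_ik a_jk / N_k
    if normalize_by_total:
        sim = sim / pm.n_phenotypes
    scores: Dict[Pair, float] = {}
    n_genes = len(pm.genes)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if sim[i, j] > 0:
                scores[pair_key(pm.genes[i], pm.genes[j])] = float(sim[i, j])
    return EvidenceDataset(
        dataset_id=dataset_id,
        kind="continuous",
        scores=scores,
        provenance="phenotype/disease co-occurrence",
        circularity_sensitive=True,
    )


def exclude_circular(datasets: Sequence[EvidenceDataset]) -> List[EvidenceDataset]:
    """Drop circularity-sensitive datasets (phenotype-prediction runs)."""
    kept = [d for d in datasets if not d.circularity_sensitive]
    dropped = [d.dataset_id for d in datasets if d.circularity_sensitive]
    if dropped:
        log.info("anti-circularity: excluded datasets %s", dropped)
    return kept
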