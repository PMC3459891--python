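"""Readers and writers for the pipeline's file formats.

Ontologies are OBO 1.2 (parsed with obonet); annotations, expression
calls, expression matrices, edge lists, ortholog maps, gold standards,
evidence datasets and networks are all tab-separated text.  Evidence
datasets and networks carry a JSON sidecar (``<path>.meta.json``) with
their identity, kind/prior and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Set, Tuple, Union

import numpy as np
import obonet
import pandas as pd

from ._util import Pair, pair_key
from .bayes import FunctionalNetwork
from .evidence import EvidenceDataset, ExpressionMatrix, OrthologMap, PhenotypeMatrix
from .gold import ExpressionCalls, GoldStandard, Ontology

PathLike = Union[str, Path]
PROPAGATED_RELATIONS = ("is_a", "part_of")


def read_obo(path: PathLike) -> Ontology:
    """Parse an OBO 1.2 file into an Ontology (is_a / part_of edges).

    Obsolete terms are skipped; other relationship types are ignored.
    """
    graph = obonet.read_obo(str(path))
    terms: Set[str] = set(graph.nodes)
    names: Dict[str, str] = {}
    parents: Dict[str, Set[str]] = {}
    for node, data in graph.nodes(data=True):
        if data.get("name"):
            names[node] = data["name"]
    # obonet edges point child -> parent, keyed by relation
    for child, parent, rel in graph.edges(keys=True):
        if rel in PROPAGATED_RELATIONS and parent in terms:
            parents.setdefault(child, set()).add(parent)
    return Ontology(terms=terms, parents=parents, names=names)


def write_obo(path: PathLike, ont: Ontology, ontology_name: str = "synthetic") -> None:
    """Write an Ontology as a minimal OBO 1.2 document (is_a edges only)."""
    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in sorted(ont.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ont.names.get(term, term)}")
        for p in sorted(ont.parents.get(term, ())):
            lines.append(f"is_a: {p} ! {ont.names.get(p, p)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_annotations(path: PathLike) -> Dict[str, Set[str]]:
    """Gene -> direct terms from a TSV of (gene_id, term_id[, evidence]).

    Comment lines starting with '!' or '#' are skipped.  Allele identifiers
    of the form ``gene<allele>`` collapse to their gene.
    """
    direct: Dict[str, Set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed annotation line: {line!r}")
        gene, term = fields[0], fields[1]
        if "<" in gene and gene.endswith(">"):  # allele -> gene collapse
            gene = gene.split("<", 1)[0]
        direct.setdefault(gene, set()).add(term)
    return direct


def write_annotations(path: PathLike, direct: Dict[str, Set[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tterm_id\n")
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_expression_calls(path: PathLike) -> ExpressionCalls:
    """Tissue presence calls from a TSV of (tissue_id, gene_id, assay_class)."""
    expressed: Dict[str, Set[str]] = {}
    assay: Dict[Tuple[str, str], str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed expression-call line: {line!r}")
        tissue, gene = fields[0], fields[1]
        cls = fields[2] if len(fields) > 2 else ""
        expressed.setdefault(tissue, set()).add(gene)
        assay[(tissue, gene)] = cls
    return ExpressionCalls(expressed=expressed, assay_class=assay)


def write_expression_calls(path: PathLike, calls: ExpressionCalls) -> None:
    with open(path, "w") as fh:
        fh.write("# tissue_id\tgene_id\tassay_class\n")
        for tissue in sorted(calls.expressed):
            for gene in sorted(calls.expressed[tissue]):
                cls = calls.assay_class.get((tissue, gene), "")
                fh.write(f"{tissue}\t{gene}\t{cls}\n")


def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    """Gene x sample matrix: first column gene_id, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_matrix(path: PathLike, m: ExpressionMatrix) -> None:
    pd.DataFrame(m.values, index=m.genes, columns=m.samples).to_csv(
        path, sep="\t", index_label="gene_id", na_rep=""
    )


def read_edge_list(path: PathLike) -> List[Tuple[str, str, str]]:
    """Interaction edges from a TSV of (gene_a, gene_b, experiment_type)."""
    edges: List[Tuple[str, str, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed edge line: {line!r}")
        edges.append((fields[0], fields[1], fields[2]))
    return edges


def read_ortholog_map(path: PathLike) -> OrthologMap:
    """Ortholog pairs from a TSV of (source_gene, target_gene)."""
    mapping: Dict[str, Set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed ortholog line: {line!r}")
        mapping.setdefault(fields[0], set()).add(fields[1])
    return OrthologMap(mapping=mapping)


def read_phenotype_annotations(path: PathLike) -> PhenotypeMatrix:
    """Gene x phenotype incidence from a TSV of (gene_id, phenotype_id)."""
    pairs = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed phenotype-annotation line: {line!r}")
        pairs.add((fields[0], fields[1]))
    genes = sorted({g for g, _ in pairs})
    phens = sorted({p for _, p in pairs})
    gidx = {g: i for i, g in enumerate(genes)}
    pidx = {p: i for i, p in enumerate(phens)}
    a = np.zeros((len(genes), len(phens)), dtype=int)
    for g, p in pairs:
        a[gidx[g], pidx[p]] = 1
    return PhenotypeMatrix(genes=genes, phenotypes=phens, a=a)


def write_gold_standard(path: PathLike, gs: GoldStandard) -> None:
    """TSV of (gene_a, gene_b, label in {1, -1}, tissue_id)."""
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tlabel\ttissue_id\n")
        for a, b in sorted(gs.positives):
            fh.write(f"{a}\t{b}\t1\t{gs.tissue}\n")
        for a, b in sorted(gs.negatives):
            fh.write(f"{a}\t{b}\t-1\t{gs.tissue}\n")


def read_gold_standard(path: PathLike) -> GoldStandard:
    positives: Set[Pair] = set()
    negatives: Set[Pair] = set()
    tissue = "GLOBAL"
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        a, b, label, tissue = line.rstrip("\n").split("\t")[:4]
        (positives if label == "1" else negatives).add(pair_key(a, b))
    return GoldStandard(tissue=tissue, positives=positives, negatives=negatives)


def write_evidence(path: PathLike, ds: EvidenceDataset) -> None:
    """TSV of (gene_a, gene_b, score) plus a JSON metadata sidecar."""
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tscore\n")
        for (a, b) in sorted(ds.scores):
            fh.write(f"{a}\t{b}\t{ds.scores[(a, b)]:.10g}\n")
    meta = {
        "dataset_id": ds.dataset_id,
        "kind": ds.kind,
        "provenance": ds.provenance,
        "circularity_sensitive": ds.circularity_sensitive,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_evidence(path: PathLike) -> EvidenceDataset:
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    scores: Dict[Pair, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        a, b, s = line.rstrip("\n").split("\t")[:3]
        scores[pair_key(a, b)] = float(s)
    return EvidenceDataset(
        dataset_id=meta["dataset_id"],
        kind=meta["kind"],
        scores=scores,
        provenance=meta.get("provenance", ""),
        circularity_sensitive=meta.get("circularity_sensitive", False),
    )


def write_network(path: PathLike, net: FunctionalNetwork, **extra) -> None:
    """TSV of (gene_a, gene_b, posterior) plus a JSON sidecar with the prior."""
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tposterior\n")
        for (a, b) in sorted(net.scores):
            fh.write(f"{a}\t{b}\t{net.scores[(a, b)]:.10g}\n")
    meta = {"tissue": net.tissue, "prior": net.prior, **extra}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_network(path: PathLike) -> FunctionalNetwork:
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    scores: Dict[Pair, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        a, b, s = line.rstrip("\n").split("\t")[:3]
        scores[pair_key(a, b)] = float(s)
    return FunctionalNetwork(tissue=meta["tissue"], prior=meta["prior"],
                             scores=scores)
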