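"""Shared fixtures: toy ontologies, gold standards and synthetic bundles."""

import numpy as np
import pytest

from tissuenet import (GoldStandard, Ontology, SynthConfig, generate,
                       propagate_annotations)


@pytest.fixture
def chain_ontology():
    """leaf -> mid -> root chain."""
    return Ontology(
        terms={"root", "mid", "leaf"},
        parents={"leaf": {"mid"}, "mid": {"root"}},
        names={"root": "root", "mid": "mid", "leaf": "leaf"},
    )


@pytest.fixture
def diamond_ontology():
    """bottom with two parents (left, right) that share one root: a DAG."""
    return Ontology(
        terms={"root", "left", "right", "bottom"},
        parents={"bottom": {"left", "right"}, "left": {"root"}, "right": {"root"}},
    )


@pytest.fixture
def toy_gold():
    """4 positives / 4 negatives over 6 genes, canonical pairs."""
    return GoldStandard(
        tissue="GLOBAL",
        positives={("a", "b"), ("a", "c"), ("b", "c"), ("d", "e")},
        negatives={("a", "d"), ("b", "e"), ("c", "f"), ("e", "f")},
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic compendium shared by integration-level tests."""
    return generate(SynthConfig(seed=7, n_genes=150, n_tissues=3, n_modules=6,
                                module_size=8, n_tissue_modules=3,
                                n_cross_pairs=600, n_background_pairs=300,
                                n_phenotypes=2))
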