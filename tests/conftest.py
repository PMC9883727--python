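"""Shared fixtures: tiny hand-built ontologies and corpora."""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import pytest

from seqgo.containers import AnnotationCorpus
from seqgo.ontology import GeneOntology, Term


def make_go(
    namespaces: Dict[str, str],
    edges: Iterable[Tuple[str, str, str]] = (),
    **kwargs,
) -> GeneOntology:
    """Build an ontology from {id: namespace} and (child, rel, parent) triples."""
    terms = {
        cls: Term(id=cls, name=f"term {cls}", namespace=ns)
        for cls, ns in namespaces.items()
    }
    return GeneOntology(terms, edges, **kwargs)


@pytest.fixture
def chain_go() -> GeneOntology:
    """C is_a B is_a A, all molecular function."""
    return make_go(
        {"GO:0000001": "MFO", "GO:0000002": "MFO", "GO:0000003": "MFO"},
        [
            ("GO:0000003", "is_a", "GO:0000002"),
            ("GO:0000002", "is_a", "GO:0000001"),
        ],
    )


@pytest.fixture
def cross_ns_go() -> GeneOntology:
    """An MFO chain whose middle class is part_of a BPO class with a BPO
    parent — the cross-namespace propagation scenario."""
    return make_go(
        {
            "GO:0000001": "MFO",  # MFO root
            "GO:0000002": "MFO",  # part_of GO:0000011
            "GO:0000010": "BPO",  # BPO root
            "GO:0000011": "BPO",
        },
        [
            ("GO:0000002", "is_a", "GO:0000001"),
            ("GO:0000011", "is_a", "GO:0000010"),
            ("GO:0000002", "part_of", "GO:0000011"),
        ],
    )


@pytest.fixture
def chain_corpus() -> AnnotationCorpus:
    return AnnotationCorpus({"P1": {"GO:0000003"}}, propagated=False)
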