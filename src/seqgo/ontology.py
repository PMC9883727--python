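"""Gene Ontology handling: OBO parsing, DAG traversal, annotation
propagation (true-path rule), class selection and information content.

The ontology is a DAG of classes in three namespaces — molecular function
(MFO), biological process (BPO) and cellular component (CCO) — connected by
typed relations (``is_a``, ``part_of``, ...).  Annotation to a class implies
annotation to all of its ancestors; propagation closes a corpus under that
rule.  Ancestor closure supports two modes:

``whole_ontology``
    follow every traversed relation, including edges that cross namespaces
    (e.g. a ``part_of`` edge from an MFO class to a BPO class);
``per_subontology``
    ignore edges whose endpoints lie in different namespaces, as in the
    CAFA3 assessment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx

from .containers import AnnotationCorpus

logger = logging.getLogger(__name__)

WHOLE_ONTOLOGY = "whole_ontology"
PER_SUBONTOLOGY = "per_subontology"
MODES = (WHOLE_ONTOLOGY, PER_SUBONTOLOGY)

#: OBO namespace strings -> short sub-ontology labels.
NAMESPACES = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
}
NAMESPACE_LONG = {v: k for k, v in NAMESPACES.items()}


class OboParseError(ValueError):
    """Malformed OBO input; the message names the offending line."""


class OntologyCycleError(ValueError):
    """The traversed relation graph contains a cycle."""


@dataclass
class Term:
    id: str
    name: str = ""
    namespace: str = ""  # MFO / BPO / CCO (empty only for obsolete stubs)
    obsolete: bool = False
    alt_ids: Tuple[str, ...] = ()
    replaced_by: Optional[str] = None


class GeneOntology:
    """The class DAG with typed relations and namespaces.

    Parameters
    ----------
    terms : mapping of class id -> Term
    edges : iterable of (child, relation, parent) triples between
        non-obsolete primary ids.
    traversed_relations : relation labels followed by traversal operations.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        edges: Iterable[Tuple[str, str, str]],
        traversed_relations: Optional[Iterable[str]] = None,
    ) -> None:
        self.terms: Dict[str, Term] = dict(terms)
        self.edges: Set[Tuple[str, str, str]] = set(edges)
        relations_present = {rel for _, rel, _ in self.edges}
        if traversed_relations is None:
            traversed_relations = relations_present | {"is_a"}
        self.traversed_relations = frozenset(traversed_relations)
        if not self.traversed_relations:
            raise ValueError("traversed_relations must be non-empty")

        self.alt_to_primary: Dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                if alt in self.alt_to_primary and self.alt_to_primary[alt] != term.id:
                    raise ValueError(
                        f"alt_id {alt} maps to both {self.alt_to_primary[alt]} "
                        f"and {term.id}"
                    )
                self.alt_to_primary[alt] = term.id

        # parent adjacency over traversed relations only
        self._parents: Dict[str, Set[str]] = {t: set() for t in self.terms}
        self._children: Dict[str, Set[str]] = {t: set() for t in self.terms}
        for child, rel, parent in self.edges:
            if rel not in self.traversed_relations:
                continue
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child}, {rel}, {parent}) references unknown term")
            if self.terms[child].obsolete or self.terms[parent].obsolete:
                raise ValueError(
                    f"edge ({child}, {rel}, {parent}) touches an obsolete term"
                )
            self._parents[child].add(parent)
            self._children[parent].add(child)

        self._check_acyclic()
        self._anc_cache: Dict[Tuple[str, str], FrozenSet[str]] = {}

    # ------------------------------------------------------------------ #

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for child, ps in self._parents.items():
            for p in ps:
                g.add_edge(child, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyCycleError(f"cycle among traversed relations: {path}")

    def resolve(self, cls: str) -> str:
        """Map an alt_id or replaced obsolete id to its usable primary id.

        Raises KeyError for ids unknown to the ontology and ValueError for
        obsolete ids without a replacement.
        """
        if cls in self.alt_to_primary:
            primary = self.alt_to_primary[cls]
            logger.info("alt_id %s resolved to primary id %s", cls, primary)
            cls = primary
        if cls not in self.terms:
            raise KeyError(f"unknown ontology class {cls}")
        term = self.terms[cls]
        if term.obsolete:
            if term.replaced_by is not None:
                return self.resolve(term.replaced_by)
            raise ValueError(f"class {cls} is obsolete with no replacement")
        return cls

    def namespace_of(self, cls: str) -> str:
        return self.terms[self.resolve(cls)].namespace

    def parents(self, cls: str, mode: str = WHOLE_ONTOLOGY) -> FrozenSet[str]:
        """Direct parents of cls over the traversed relations."""
        cls = self.resolve(cls)
        ps = self._parents[cls]
        if mode == PER_SUBONTOLOGY:
            ns = self.terms[cls].namespace
            ps = {p for p in ps if self.terms[p].namespace == ns}
        elif mode != WHOLE_ONTOLOGY:
            raise ValueError(f"unknown mode {mode!r}")
        return frozenset(ps)

    def children(self, cls: str, mode: str = WHOLE_ONTOLOGY) -> FrozenSet[str]:
        cls = self.resolve(cls)
        cs = self._children[cls]
        if mode == PER_SUBONTOLOGY:
            ns = self.terms[cls].namespace
            cs = {c for c in cs if self.terms[c].namespace == ns}
        elif mode != WHOLE_ONTOLOGY:
            raise ValueError(f"unknown mode {mode!r}")
        return frozenset(cs)

    def ancestors(self, cls: str, mode: str = WHOLE_ONTOLOGY) -> FrozenSet[str]:
        """Transitive closure of parents; excludes cls itself."""
        cls = self.resolve(cls)
        key = (cls, mode)
        cached = self._anc_cache.get(key)
        if cached is not None:
            return cached
        out: Set[str] = set()
        stack = list(self.parents(cls, mode))
        while stack:
            p = stack.pop()
            if p in out:
                continue
            out.add(p)
            stack.extend(self.parents(p, mode) - out)
        result = frozenset(out)
        self._anc_cache[key] = result
        return result

    def descendants(self, cls: str, mode: str = WHOLE_ONTOLOGY) -> FrozenSet[str]:
        cls = self.resolve(cls)
        out: Set[str] = set()
        stack = list(self.children(cls, mode))
        while stack:
            c = stack.pop()
            if c in out:
                continue
            out.add(c)
            stack.extend(self.children(c, mode) - out)
        return frozenset(out)

    def active_terms(self) -> List[str]:
        """Sorted non-obsolete primary class ids."""
        return sorted(t for t, info in self.terms.items() if not info.obsolete)

    def roots(self) -> List[str]:
        return sorted(
            t for t in self.active_terms() if not self._parents[t]
        )

    def leaves(self) -> List[str]:
        """Non-obsolete classes with no children under traversed relations."""
        return sorted(t for t in self.active_terms() if not self._children[t])

    def classes_in_namespace(self, namespace: str) -> List[str]:
        return sorted(
            t for t in self.active_terms() if self.terms[t].namespace == namespace
        )

    def __contains__(self, cls: str) -> bool:
        return cls in self.terms or cls in self.alt_to_primary

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------- #
# OBO 1.2 flat-file reading / writing
# ---------------------------------------------------------------------- #


def load_obo(
    path: str,
    traversed_relations: Optional[Iterable[str]] = None,
) -> GeneOntology:
    """Parse an OBO 1.2 flat file into a :class:`GeneOntology`.

    Obsolete terms are retained but flagged; edges are kept only between
    non-obsolete primary ids.  ``traversed_relations`` defaults to every
    relationship type present in the file plus ``is_a``.  A cycle among the
    traversed relations raises :class:`OntologyCycleError` listing the cycle.
    """
    terms: Dict[str, Term] = {}
    raw_edges: List[Tuple[str, str, str]] = []

    stanza: Optional[Dict[str, List[Tuple[str, int]]]] = None
    stanza_type = ""

    def flush() -> None:
        nonlocal stanza
        if stanza is None or stanza_type != "Term":
            stanza = None
            return
        ids = stanza.get("id", [])
        if not ids:
            line_no = min(ln for vals in stanza.values() for _, ln in vals)
            raise OboParseError(f"[Term] stanza near line {line_no} has no id")
        term_id = ids[0][0]
        name = stanza.get("name", [("", 0)])[0][0]
        ns_raw = stanza.get("namespace", [("", 0)])[0][0]
        namespace = NAMESPACES.get(ns_raw, ns_raw)
        obsolete = any(v.lower() == "true" for v, _ in stanza.get("is_obsolete", []))
        alt_ids = tuple(v for v, _ in stanza.get("alt_id", []))
        replaced = stanza.get("replaced_by")
        replaced_by = replaced[0][0] if replaced else None
        terms[term_id] = Term(
            id=term_id,
            name=name,
            namespace=namespace,
            obsolete=obsolete,
            alt_ids=alt_ids,
            replaced_by=replaced_by,
        )
        if not obsolete:
            for value, line_no in stanza.get("is_a", []):
                parent = value.split("!")[0].strip()
                if not parent:
                    raise OboParseError(f"line {line_no}: empty is_a target")
                raw_edges.append((term_id, "is_a", parent))
            for value, line_no in stanza.get("relationship", []):
                parts = value.split("!")[0].split()
                if len(parts) != 2:
                    raise OboParseError(
                        f"line {line_no}: malformed relationship {value!r}"
                    )
                rel, parent = parts
                raw_edges.append((term_id, rel, parent))
        stanza = None

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(f"line {line_no}: malformed stanza header {line!r}")
                flush()
                stanza_type = line[1:-1]
                stanza = {}
                continue
            if ":" not in line:
                raise OboParseError(f"line {line_no}: expected 'key: value', got {line!r}")
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if stanza is not None:
                stanza.setdefault(key, []).append((value, line_no))
        flush()

    # resolve edge targets through alt_ids; drop edges to unknown/obsolete
    alt: Dict[str, str] = {}
    for t in terms.values():
        for a in t.alt_ids:
            alt[a] = t.id
    edges: Set[Tuple[str, str, str]] = set()
    for child, rel, parent in raw_edges:
        parent = alt.get(parent, parent)
        if parent not in terms:
            logger.warning("dropping edge to unknown term: (%s, %s, %s)", child, rel, parent)
            continue
        if terms[parent].obsolete:
            logger.warning("dropping edge to obsolete term: (%s, %s, %s)", child, rel, parent)
            continue
        edges.add((child, rel, parent))

    return GeneOntology(terms, edges, traversed_relations)


def write_obo(go: GeneOntology, path: str) -> None:
    """Serialize to OBO 1.2; round-trips through :func:`load_obo`."""
    by_child: Dict[str, List[Tuple[str, str]]] = {}
    for child, rel, parent in sorted(go.edges):
        by_child.setdefault(child, []).append((rel, parent))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term_id in sorted(go.terms):
            term = go.terms[term_id]
            fh.write(f"\n[Term]\nid: {term.id}\n")
            if term.name:
                fh.write(f"name: {term.name}\n")
            if term.namespace:
                fh.write(f"namespace: {NAMESPACE_LONG.get(term.namespace, term.namespace)}\n")
            for a in term.alt_ids:
                fh.write(f"alt_id: {a}\n")
            for rel, parent in by_child.get(term_id, []):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")
                if term.replaced_by:
                    fh.write(f"replaced_by: {term.replaced_by}\n")


# ---------------------------------------------------------------------- #
# Propagation, class selection, information content
# ---------------------------------------------------------------------- #


def propagate(
    ann: AnnotationCorpus,
    go: GeneOntology,
    mode: str = WHOLE_ONTOLOGY,
    on_unknown: str = "warn",
) -> AnnotationCorpus:
    """Close every protein's class set under the ancestor relation.

    Idempotent and extensive: the output contains the input per protein, and
    propagating twice equals propagating once.  Annotations to obsolete
    classes are remapped via replaced_by when present, otherwise dropped
    with a warning.  Unknown class ids are skipped with a warning by default
    (``on_unknown="error"`` raises instead).
    """
    if on_unknown not in ("warn", "error"):
        raise ValueError("on_unknown must be 'warn' or 'error'")
    out: Dict[str, Set[str]] = {}
    for protein, classes in ann.records.items():
        closed: Set[str] = set()
        for cls in classes:
            try:
                primary = go.resolve(cls)
            except KeyError:
                if on_unknown == "error":
                    raise
                logger.warning("skipping unknown class %s on %s", cls, protein)
                continue
            except ValueError:
                logger.warning(
                    "dropping annotation of %s to obsolete class %s", protein, cls
                )
                continue
            closed.add(primary)
            closed |= go.ancestors(primary, mode)
        if closed:
            out[protein] = closed
    return AnnotationCorpus(out, propagated=True, evidence=ann.evidence)


def select_classes(ann: AnnotationCorpus, min_count: int = 50) -> List[str]:
    """Classes annotated to ``min_count`` or more distinct proteins.

    Requires a propagated corpus (counts are meaningless before closure).
    The returned list is lexicographic, and defines the output coordinate
    order of the convolutional classifier.
    """
    if not ann.propagated:
        raise ValueError("select_classes requires a propagated corpus")
    counts = ann.class_counts()
    return sorted(c for c, n in counts.items() if n >= min_count)


@dataclass
class ICTable:
    """Per-class information content IC(c) = -ln Pr(c | parents(c)).

    ``Pr(c | P(c))`` is estimated from a propagated training corpus as the
    number of proteins annotated with c over the number annotated with the
    conjunction of all direct parents of c; with add-one smoothing both
    counts are incremented so classes absent from the corpus stay finite.
    Parentless classes (roots) have IC 0.
    """

    ic: Dict[str, float]
    corpus_size: int

    def __getitem__(self, cls: str) -> float:
        return self.ic[cls]

    def __contains__(self, cls: str) -> bool:
        return cls in self.ic

    def get(self, cls: str, default: Optional[float] = None) -> Optional[float]:
        return self.ic.get(cls, default)

    def total(self, classes: Iterable[str]) -> float:
        return sum(self.ic[c] for c in classes)


def compute_ic(
    ann: AnnotationCorpus,
    go: GeneOntology,
    smoothing: bool = True,
) -> ICTable:
    """Estimate information content for every active class in the ontology.

    With smoothing off, a class whose parent conjunction has zero corpus
    support raises an error naming the class.
    """
    if not ann.propagated:
        raise ValueError("compute_ic requires a propagated corpus")
    if len(ann) == 0:
        raise ValueError("compute_ic requires a non-empty corpus")
    s = 1 if smoothing else 0
    counts = ann.class_counts()
    protein_sets = list(ann.records.values())
    ic: Dict[str, float] = {}
    for cls in go.active_terms():
        parents = go.parents(cls, WHOLE_ONTOLOGY)
        if not parents:
            ic[cls] = 0.0
            continue
        n_c = counts.get(cls, 0)
        n_parents = sum(1 for ps in protein_sets if parents <= ps)
        if n_parents + s == 0:
            raise ValueError(
                f"class {cls}: no protein is annotated with all parents "
                "and smoothing is off"
            )
        if n_c + s == 0:
            # absent from the corpus: IC undefined without smoothing
            continue
        p = (n_c + s) / (n_parents + s)
        # propagation guarantees n_c <= n_parents, so p <= 1 and IC >= 0
        ic[cls] = max(0.0, -math.log(p))
    return ICTable(ic=ic, corpus_size=len(ann))


def ancestors(go: GeneOntology, cls: str, mode: str = WHOLE_ONTOLOGY) -> FrozenSet[str]:
    """Module-level convenience for :meth:`GeneOntology.ancestors`."""
    return go.ancestors(cls, mode)
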