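"""Desk-scale synthetic benchmark generator.

Generates data with the statistical structure the predictor assumes: a toy
GO-like DAG across the three namespaces, proteins whose sequences carry
class-specific planted motifs (leaf classes carry the motifs; internal
classes gain signal purely through propagation, mirroring GO's convention
of annotating to the most specific class), and a homology table whose
bitscores reflect shared leaf annotations (standing in for an actual
similarity search, so tests need no aligner).

Every operation is deterministic per seed; each stage draws from its own
seed stream derived from the top-level seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cnn import AA_ALPHABET
from .containers import AnnotationCorpus, Hit, SequenceRecord, SimilarityTable
from .dataio import (
    write_annotations,
    write_blast_tab,
    write_fasta,
)
from .ontology import GeneOntology, Term, WHOLE_ONTOLOGY, propagate, write_obo


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    Defaults describe the standard benchmark: 500 proteins of 100–400
    residues over a 45-term ontology (15 terms per namespace), 1–3 planted
    motifs of 8–24 residues per protein, 2% per-residue mutation inside
    planted motifs, uniform background composition.
    """

    n_terms_per_namespace: int = 15
    n_proteins: int = 500
    seq_length: Tuple[int, int] = (100, 400)
    motif_length: Tuple[int, int] = (8, 24)
    motifs_per_protein: Tuple[int, int] = (1, 3)
    mutation_rate: float = 0.02
    part_of_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seq_length", "motif_length", "motifs_per_protein"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is empty: {lo}..{hi}")
        if self.motif_length[1] > self.seq_length[0]:
            raise ValueError("motifs must fit in the shortest sequence")
        if self.motifs_per_protein[1] * self.motif_length[1] > self.seq_length[0]:
            raise ValueError(
                "the maximum total motif length must fit non-overlapping in "
                "the shortest sequence"
            )


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


# ---------------------------------------------------------------------- #
# Ontology
# ---------------------------------------------------------------------- #


def make_toy_ontology(spec: SyntheticSpec) -> GeneOntology:
    """A small acyclic DAG: one root per namespace; each later term gets
    1–2 is_a parents among earlier terms of its namespace; MFO terms gain
    a part_of edge to a BPO term with a small probability."""
    rng = _rng(spec, 1)
    terms: Dict[str, Term] = {}
    edges: List[Tuple[str, str, str]] = []
    ids_by_ns: Dict[str, List[str]] = {}
    counter = 0
    for ns in ("MFO", "BPO", "CCO"):
        ids: List[str] = []
        for i in range(spec.n_terms_per_namespace):
            counter += 1
            term_id = f"GO:{counter:07d}"
            terms[term_id] = Term(
                id=term_id, name=f"synthetic {ns.lower()} term {i}", namespace=ns
            )
            if ids:  # non-root: 1-2 parents among earlier terms
                n_parents = int(rng.integers(1, 3))
                n_parents = min(n_parents, len(ids))
                parents = rng.choice(len(ids), size=n_parents, replace=False)
                for p in parents:
                    edges.append((term_id, "is_a", ids[int(p)]))
            ids.append(term_id)
        ids_by_ns[ns] = ids
    for term_id in ids_by_ns["MFO"][1:]:
        if rng.random() < spec.part_of_probability:
            target = ids_by_ns["BPO"][int(rng.integers(len(ids_by_ns["BPO"])))]
            edges.append((term_id, "part_of", target))
    return GeneOntology(terms, edges)


def make_motif_map(go: GeneOntology, spec: SyntheticSpec) -> Dict[str, str]:
    """A distinct random motif for every leaf class."""
    rng = _rng(spec, 2)
    alphabet = np.array(list(AA_ALPHABET))
    motifs: Dict[str, str] = {}
    used: set = set()
    for leaf in go.leaves():
        while True:
            length = int(rng.integers(spec.motif_length[0], spec.motif_length[1] + 1))
            motif = "".join(rng.choice(alphabet, size=length))
            if motif not in used:
                used.add(motif)
                motifs[leaf] = motif
                break
    return motifs


# ---------------------------------------------------------------------- #
# Proteins
# ---------------------------------------------------------------------- #


def simulate_proteins(
    go: GeneOntology,
    motif_map: Mapping[str, str],
    spec: SyntheticSpec,
    return_occurrences: bool = False,
):
    """Motif-bearing proteins with leaf-level raw annotations.

    Each protein draws 1–3 leaf classes; its sequence is uniform background
    with each chosen class's motif inserted once at a uniformly chosen
    non-overlapping position, each motif residue independently mutated with
    probability ``mutation_rate``.  Raw annotations carry evidence code
    IDA; the returned truth corpus is the whole-ontology propagation of the
    raw corpus.

    Returns (records, raw corpus, truth corpus); with
    ``return_occurrences`` a fourth item maps protein id -> list of
    (class, start, end) planted intervals.
    """
    rng = _rng(spec, 3)
    leaves = sorted(motif_map)
    if not leaves:
        raise ValueError("motif map is empty")
    alphabet = np.array(list(AA_ALPHABET))
    width = len(str(spec.n_proteins))
    records: List[SequenceRecord] = []
    raw: Dict[str, FrozenSet[str]] = {}
    evidence: Dict[Tuple[str, str], str] = {}
    occurrences: Dict[str, List[Tuple[str, int, int]]] = {}
    lo_k, hi_k = spec.motifs_per_protein
    for i in range(spec.n_proteins):
        pid = f"P{i + 1:0{width}d}"
        k = int(rng.integers(lo_k, hi_k + 1))
        k = min(k, len(leaves))
        chosen = [leaves[int(j)] for j in rng.choice(len(leaves), size=k, replace=False)]
        length = int(rng.integers(spec.seq_length[0], spec.seq_length[1] + 1))
        seq = rng.choice(alphabet, size=length)
        placed: List[Tuple[int, int]] = []
        occ: List[Tuple[str, int, int]] = []
        for cls in chosen:
            motif = motif_map[cls]
            m = len(motif)
            for _ in range(10000):
                start = int(rng.integers(0, length - m + 1))
                if all(start + m <= a or start >= b for a, b in placed):
                    break
            else:  # spec validation makes placement feasible; guard anyway
                raise RuntimeError(f"could not place motif for {cls} in {pid}")
            placed.append((start, start + m))
            residues = np.array(list(motif))
            mutate = rng.random(m) < spec.mutation_rate
            if mutate.any():
                residues[mutate] = rng.choice(alphabet, size=int(mutate.sum()))
            seq[start : start + m] = residues
            occ.append((cls, start, start + m))
        records.append(SequenceRecord(id=pid, sequence="".join(seq)))
        raw[pid] = frozenset(chosen)
        for cls in chosen:
            evidence[(pid, cls)] = "IDA"
        occurrences[pid] = occ
    raw_corpus = AnnotationCorpus(raw, propagated=False, evidence=evidence)
    truth = propagate(raw_corpus, go, WHOLE_ONTOLOGY)
    if return_occurrences:
        return records, raw_corpus, truth, occurrences
    return records, raw_corpus, truth


# ---------------------------------------------------------------------- #
# Similarity
# ---------------------------------------------------------------------- #


def simulate_similarity(
    annotations: AnnotationCorpus,
    spec: SyntheticSpec,
    max_hits: int = 50,
) -> SimilarityTable:
    """A homology table consistent with shared annotations.

    ``annotations`` is the raw leaf-level corpus (shared-class counts are
    taken over its class sets).  Each ordered pair sharing >= 1 class gets a
    hit with bitscore 40 x (shared classes) + Normal(0, 5), truncated below
    at 25; non-sharing pairs get a noise hit with probability 1%, bitscore
    Uniform(25, 35).  E-value = 10^(-bitscore/10); queries keep their top
    ``max_hits`` hits by bitscore.
    """
    rng = _rng(spec, 4)
    proteins = annotations.proteins
    classes = sorted(annotations.classes())
    col = {c: j for j, c in enumerate(classes)}
    n = len(proteins)
    b = np.zeros((n, len(classes)), dtype=np.int32)
    for i, p in enumerate(proteins):
        for c in annotations[p]:
            b[i, col[c]] = 1
    shared = b @ b.T  # (n, n) shared class counts
    noise = rng.normal(0.0, 5.0, size=(n, n))
    bitscore = np.maximum(25.0, 40.0 * shared + noise)
    background = rng.random((n, n)) < 0.01
    bg_scores = rng.uniform(25.0, 35.0, size=(n, n))
    hits: Dict[str, List[Hit]] = {}
    for i, query in enumerate(proteins):
        row: List[Hit] = []
        for j, subject in enumerate(proteins):
            if i == j:
                continue
            if shared[i, j] > 0:
                bs = float(bitscore[i, j])
            elif background[i, j]:
                bs = float(bg_scores[i, j])
            else:
                continue
            row.append(Hit(subject=subject, bitscore=bs, evalue=10.0 ** (-bs / 10.0)))
        row.sort(key=lambda h: (-h.bitscore, h.subject))
        if row:
            hits[query] = row[:max_hits]
    return SimilarityTable(hits)


# ---------------------------------------------------------------------- #
# Bundled dataset and serialization
# ---------------------------------------------------------------------- #


@dataclass
class SyntheticDataset:
    """Everything one experiment needs, with a train/test protein split."""

    spec: SyntheticSpec
    go: GeneOntology
    motif_map: Dict[str, str]
    records: List[SequenceRecord]
    raw: AnnotationCorpus
    truth: AnnotationCorpus
    occurrences: Dict[str, List[Tuple[str, int, int]]]
    similarity: SimilarityTable
    train_ids: List[str]
    test_ids: List[str]

    @property
    def records_by_id(self) -> Dict[str, SequenceRecord]:
        return {r.id: r for r in self.records}

    def train_records(self) -> List[SequenceRecord]:
        by_id = self.records_by_id
        return [by_id[p] for p in self.train_ids]

    def test_records(self) -> List[SequenceRecord]:
        by_id = self.records_by_id
        return [by_id[p] for p in self.test_ids]


def simulate_dataset(
    spec: SyntheticSpec, test_fraction: float = 0.2
) -> SyntheticDataset:
    """Run the full generator and split proteins into train/test."""
    go = make_toy_ontology(spec)
    motif_map = make_motif_map(go, spec)
    records, raw, truth, occurrences = simulate_proteins(
        go, motif_map, spec, return_occurrences=True
    )
    similarity = simulate_similarity(raw, spec)
    rng = _rng(spec, 5)
    ids = [r.id for r in records]
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test_ids = sorted(ids[int(i)] for i in perm[:n_test])
    train_ids = sorted(ids[int(i)] for i in perm[n_test:])
    return SyntheticDataset(
        spec=spec,
        go=go,
        motif_map=motif_map,
        records=records,
        raw=raw,
        truth=truth,
        occurrences=occurrences,
        similarity=similarity,
        train_ids=train_ids,
        test_ids=test_ids,
    )


def motif_recovery_rate(
    model,
    dataset: SyntheticDataset,
    proteins: Optional[Sequence[str]] = None,
    top: int = 10,
) -> float:
    """Fraction of (protein, positive class) pairs whose class-associated
    filters fire on a planted motif.

    For each protein (default: the test split) and each of the model's
    classes it is truly annotated with, take the ``top`` filters most
    associated with the class (largest dense weight into its output unit)
    and check whether any of their best-activating windows overlaps a
    planted motif interval in that protein's sequence.
    """
    if proteins is None:
        proteins = dataset.test_ids
    by_id = dataset.records_by_id
    term_set = frozenset(model.terms)
    hits = 0
    total = 0
    for pid in proteins:
        truth_classes = dataset.truth.records.get(pid, frozenset()) & term_set
        if not truth_classes:
            continue
        acts = model.filter_activations(by_id[pid].sequence)
        by_index = {a.index: a for a in acts}
        intervals = [(a, b) for _, a, b in dataset.occurrences[pid]]
        for cls in truth_classes:
            total += 1
            windows = [
                by_index[i] for i in model.top_filters_for_class(cls, top=top)
                if i in by_index
            ]
            overlap = any(
                w.position < b and w.position + w.length > a
                for w in windows
                for a, b in intervals
            )
            if overlap:
                hits += 1
    if total == 0:
        raise ValueError("no positive (protein, class) pairs to score")
    return hits / total


def write_dataset(dataset: SyntheticDataset, out_dir: str) -> None:
    """Serialize the bundle to standard formats: go.obo, train/test FASTA
    and annotation TSVs, and an outfmt-6 similarity table."""
    os.makedirs(out_dir, exist_ok=True)
    write_obo(dataset.go, os.path.join(out_dir, "go.obo"))
    by_id = dataset.records_by_id
    train = frozenset(dataset.train_ids)
    test = frozenset(dataset.test_ids)
    write_fasta(dataset.train_records(), os.path.join(out_dir, "train.fasta"))
    write_fasta(dataset.test_records(), os.path.join(out_dir, "test.fasta"))
    write_annotations(
        dataset.raw.restrict_proteins(train), os.path.join(out_dir, "train_annots.tsv")
    )
    write_annotations(
        dataset.raw.restrict_proteins(test), os.path.join(out_dir, "test_annots.tsv")
    )
    write_blast_tab(dataset.similarity, os.path.join(out_dir, "diamond.tsv"))
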