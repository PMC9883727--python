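"""In-memory containers shared across the package.

These are deliberately thin: a sequence record, an annotation corpus
(protein -> set of GO class ids, raw or ancestor-closed), a similarity table
(per-query ranked homology hits), and a prediction set (protein -> class ->
score in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence.

    Attributes
    ----------
    id : str
        Non-empty protein identifier, unique within a file.
    sequence : str
        Upper-case amino-acid text, length >= 1.  Any letters are permitted;
        non-standard residues are handled downstream by the encoder.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


class AnnotationCorpus:
    """Protein -> set of GO class ids, with optional evidence provenance.

    A corpus is either *raw* (as read from an annotation file) or
    *propagated* (each protein's class set closed under the ontology's
    ancestor relation — the true-path rule).  The flag is carried on the
    object and checked by operations that require one state or the other.
    """

    def __init__(
        self,
        records: Mapping[str, Iterable[str]],
        propagated: bool = False,
        evidence: Optional[Mapping[Tuple[str, str], str]] = None,
    ) -> None:
        self.records: Dict[str, FrozenSet[str]] = {}
        for protein, classes in records.items():
            classes = frozenset(classes)
            if not classes:
                continue  # no empty class sets, per the container invariant
            self.records[protein] = classes
        self.propagated = bool(propagated)
        self.evidence: Dict[Tuple[str, str], str] = dict(evidence or {})

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein: str) -> bool:
        return protein in self.records

    def __getitem__(self, protein: str) -> FrozenSet[str]:
        return self.records[protein]

    @property
    def proteins(self) -> List[str]:
        return sorted(self.records)

    def classes(self) -> FrozenSet[str]:
        """Union of all annotated class ids."""
        out: set = set()
        for s in self.records.values():
            out |= s
        return frozenset(out)

    def class_counts(self) -> Dict[str, int]:
        """Distinct-protein annotation count per class."""
        counts: Dict[str, int] = {}
        for s in self.records.values():
            for c in s:
                counts[c] = counts.get(c, 0) + 1
        return counts

    def restrict_classes(self, keep: Iterable[str]) -> "AnnotationCorpus":
        keep = frozenset(keep)
        return AnnotationCorpus(
            {p: s & keep for p, s in self.records.items()},
            propagated=self.propagated,
        )

    def restrict_proteins(self, keep: Iterable[str]) -> "AnnotationCorpus":
        keep = frozenset(keep)
        return AnnotationCorpus(
            {p: s for p, s in self.records.items() if p in keep},
            propagated=self.propagated,
            evidence={k: v for k, v in self.evidence.items() if k[0] in keep},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCorpus):
            return NotImplemented
        return self.records == other.records and self.propagated == other.propagated

    def __repr__(self) -> str:
        state = "propagated" if self.propagated else "raw"
        return f"AnnotationCorpus({len(self.records)} proteins, {state})"


@dataclass(frozen=True)
class Hit:
    """One similarity-search hit for a query."""

    subject: str
    bitscore: float
    evalue: float


class SimilarityTable:
    """Per-query homology hits, sorted by descending bitscore.

    Invariants maintained by the constructor: hits sorted by descending
    bitscore (ties broken by subject id), duplicate (query, subject) pairs
    collapsed to the maximum bitscore.
    """

    def __init__(self, hits: Mapping[str, Iterable[Hit]]) -> None:
        self.hits: Dict[str, List[Hit]] = {}
        for query, hs in hits.items():
            best: Dict[str, Hit] = {}
            for h in hs:
                prev = best.get(h.subject)
                if prev is None or h.bitscore > prev.bitscore:
                    best[h.subject] = h
            if best:
                self.hits[query] = sorted(
                    best.values(), key=lambda h: (-h.bitscore, h.subject)
                )

    def __len__(self) -> int:
        return len(self.hits)

    def __contains__(self, query: str) -> bool:
        return query in self.hits

    def __getitem__(self, query: str) -> List[Hit]:
        return self.hits[query]

    @property
    def queries(self) -> List[str]:
        return sorted(self.hits)


class PredictionSet:
    """Protein -> class -> prediction score in [0, 1].

    Thresholding at t yields the predicted class set P_i(t) = {f : score > t}
    (strict inequality).
    """

    def __init__(self, scores: Mapping[str, Mapping[str, float]]) -> None:
        self.scores: Dict[str, Dict[str, float]] = {}
        for protein, table in scores.items():
            clean: Dict[str, float] = {}
            for cls, s in table.items():
                s = float(s)
                if not (0.0 <= s <= 1.0):
                    raise ValueError(
                        f"score {s} for ({protein}, {cls}) outside [0, 1]"
                    )
                clean[cls] = s
            self.scores[protein] = clean

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, protein: str) -> bool:
        return protein in self.scores

    def __getitem__(self, protein: str) -> Dict[str, float]:
        return self.scores[protein]

    @property
    def proteins(self) -> List[str]:
        return sorted(self.scores)

    def classes(self) -> FrozenSet[str]:
        out: set = set()
        for table in self.scores.values():
            out |= set(table)
        return frozenset(out)

    def threshold(self, t: float) -> Dict[str, FrozenSet[str]]:
        """P_i(t) per protein (strict: score > t)."""
        return {
            p: frozenset(c for c, s in table.items() if s > t)
            for p, table in self.scores.items()
        }

    def restrict_classes(self, keep: Iterable[str]) -> "PredictionSet":
        keep = frozenset(keep)
        return PredictionSet(
            {
                p: {c: s for c, s in table.items() if c in keep}
                for p, table in self.scores.items()
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionSet):
            return NotImplemented
        return self.scores == other.scores

    def __repr__(self) -> str:
        return f"PredictionSet({len(self.scores)} proteins, {len(self.classes())} classes)"
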