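"""Frequency and homology-transfer baseline predictors.

Three predictors, all operating on a propagated training corpus:

* **naive** — every target gets the same score map, the training-corpus
  annotation frequency S(p, f) = N_f / N_total.  Because propagation piles
  annotations onto high-level classes, this floor is surprisingly strong in
  protein-centric evaluations.
* **diamond_blast** — annotation transfer weighted by the single best hit:
  S(q, f) = max_s bitscore(q, s) * I(f in T_s) / max_s bitscore(q, s).
* **diamond_score** — transfer weighted by all hits:
  S(q, f) = sum_s I(f in T_s) * bitscore(q, s) / sum_s bitscore(q, s).

T_s is the propagated annotation set of training protein s.  Hits whose
subject has no training annotation are excluded from numerator and
denominator alike (their T_s is undefined).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List

from .containers import AnnotationCorpus, PredictionSet, SimilarityTable

logger = logging.getLogger(__name__)


def _require_propagated(train: AnnotationCorpus) -> None:
    if not train.propagated:
        raise ValueError("baseline predictors require a propagated training corpus")
    if len(train) == 0:
        raise ValueError("training corpus is empty")


def naive_scores(train: AnnotationCorpus, targets: Iterable[str]) -> PredictionSet:
    """Annotation-frequency predictor: identical scores for every target."""
    _require_propagated(train)
    n_total = len(train)
    freq = {cls: n / n_total for cls, n in train.class_counts().items()}
    return PredictionSet({target: dict(freq) for target in targets})


def diamond_blast_scores(
    hits: SimilarityTable, train: AnnotationCorpus
) -> PredictionSet:
    """Best-hit annotation transfer, normalized by the top bitscore.

    When several hits tie at the maximal bitscore, a class scores 1 if any
    of them carries it (the max over products already implies this).
    Queries with no usable hits are absent from the output.
    """
    _require_propagated(train)
    scores: Dict[str, Dict[str, float]] = {}
    for query in hits.queries:
        usable = [h for h in hits[query] if h.subject in train]
        skipped = len(hits[query]) - len(usable)
        if skipped:
            logger.info("%s: ignored %d hits to unannotated subjects", query, skipped)
        if not usable:
            continue
        top = max(h.bitscore for h in usable)
        table: Dict[str, float] = {}
        for h in usable:
            for cls in train[h.subject]:
                contrib = h.bitscore / top
                if contrib > table.get(cls, 0.0):
                    table[cls] = contrib
        scores[query] = table
    return PredictionSet(scores)


def diamond_score(hits: SimilarityTable, train: AnnotationCorpus) -> PredictionSet:
    """All-hit annotation transfer, normalized by the bitscore sum."""
    _require_propagated(train)
    scores: Dict[str, Dict[str, float]] = {}
    for query in hits.queries:
        usable = [h for h in hits[query] if h.subject in train]
        if not usable:
            continue
        denom = sum(h.bitscore for h in usable)
        numer: Dict[str, float] = {}
        for h in usable:
            for cls in train[h.subject]:
                numer[cls] = numer.get(cls, 0.0) + h.bitscore
        scores[query] = {cls: min(1.0, v / denom) for cls, v in numer.items()}
    return PredictionSet(scores)
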