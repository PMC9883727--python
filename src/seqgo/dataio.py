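"""Readers and writers for every on-disk format the tool touches.

Formats: FASTA (sequences), 3-column annotation TSV (protein, GO id,
evidence code), BLAST/DIAMOND tabular ``outfmt 6`` similarity tables,
3-column prediction TSV, and the CAFA submission format.  Filtering rules —
experimental evidence codes, the e-value cutoff — are applied at load time.
All readers fail loudly with line numbers on malformed input.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from Bio import SeqIO

from .containers import AnnotationCorpus, Hit, PredictionSet, SequenceRecord, SimilarityTable

logger = logging.getLogger(__name__)

#: Evidence codes treated as experimental (CAFA convention).
EXPERIMENTAL_CODES = frozenset(
    ["EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"]
)

GO_ID_RE = re.compile(r"^GO:\d{7}$")


# ---------------------------------------------------------------------- #
# FASTA
# ---------------------------------------------------------------------- #


def read_fasta(path: str) -> List[SequenceRecord]:
    """One record per header; sequences upper-cased, whitespace stripped.

    Duplicate ids and empty sequences are errors.
    """
    records: List[SequenceRecord] = []
    seen: Set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------- #
# Annotations
# ---------------------------------------------------------------------- #


def read_annotations(path: str, experimental_only: bool = True) -> AnnotationCorpus:
    """Read a 3-column TSV (protein id, GO id, evidence code).

    When ``experimental_only`` is set, rows whose evidence code is not in
    :data:`EXPERIMENTAL_CODES` are dropped.  The returned corpus is raw
    (unpropagated).
    """
    records: Dict[str, Set[str]] = {}
    evidence: Dict[Tuple[str, str], str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{line_no}: expected 3 tab-separated columns, got {len(parts)}"
                )
            protein, go_id, code = (p.strip() for p in parts)
            if not GO_ID_RE.match(go_id):
                raise ValueError(f"{path}:{line_no}: malformed GO id {go_id!r}")
            if experimental_only and code not in EXPERIMENTAL_CODES:
                continue
            records.setdefault(protein, set()).add(go_id)
            evidence[(protein, go_id)] = code
    return AnnotationCorpus(records, propagated=False, evidence=evidence)


def write_annotations(ann: AnnotationCorpus, path: str, default_code: str = "IDA") -> None:
    """Write a corpus back to the 3-column TSV format."""
    with open(path, "w") as fh:
        for protein in ann.proteins:
            for cls in sorted(ann[protein]):
                code = ann.evidence.get((protein, cls), default_code)
                fh.write(f"{protein}\t{cls}\t{code}\n")


# ---------------------------------------------------------------------- #
# Similarity tables (BLAST / DIAMOND outfmt 6)
# ---------------------------------------------------------------------- #


def read_blast_tab(
    path: str,
    evalue_cutoff: float = 0.001,
    drop_self: bool = True,
) -> SimilarityTable:
    """Read a 12-column tabular similarity search result.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Hits with e-value above the cutoff are
    removed; self-hits optionally dropped; duplicate (query, subject) pairs
    keep the maximum bitscore; per-query hits end up sorted by descending
    bitscore.
    """
    hits: Dict[str, List[Hit]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{line_no}: expected 12 tab-separated columns, got {len(parts)}"
                )
            query, subject = parts[0], parts[1]
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{line_no}: non-numeric evalue/bitscore: {exc}"
                ) from None
            if evalue > evalue_cutoff:
                continue
            if drop_self and query == subject:
                continue
            hits.setdefault(query, []).append(
                Hit(subject=subject, bitscore=bitscore, evalue=evalue)
            )
    return SimilarityTable(hits)


def write_blast_tab(table: SimilarityTable, path: str) -> None:
    """Serialize a similarity table back to outfmt-6 (alignment coordinate
    columns are filled with placeholders; only ids, e-value and bitscore are
    meaningful)."""
    with open(path, "w") as fh:
        for query in table.queries:
            for h in table[query]:
                fh.write(
                    "\t".join(
                        [
                            query,
                            h.subject,
                            "0.0",  # pident
                            "0",  # length
                            "0",  # mismatch
                            "0",  # gapopen
                            "0",  # qstart
                            "0",  # qend
                            "0",  # sstart
                            "0",  # send
                            f"{h.evalue:.3g}",
                            f"{h.bitscore:.1f}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------- #
# Predictions
# ---------------------------------------------------------------------- #

PREDICTION_HEADER = "protein\tclass\tscore"


def write_predictions(
    preds: PredictionSet, path: str, min_report_score: float = 0.01
) -> None:
    """TSV of (protein, class, score) rounded to 3 decimals; scores below
    ``min_report_score`` are omitted."""
    with open(path, "w") as fh:
        fh.write(PREDICTION_HEADER + "\n")
        for protein in preds.proteins:
            for cls in sorted(preds[protein]):
                score = preds[protein][cls]
                if score < min_report_score:
                    continue
                fh.write(f"{protein}\t{cls}\t{round(score, 3):.3f}\n")


def read_predictions(path: str) -> PredictionSet:
    scores: Dict[str, Dict[str, float]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line == PREDICTION_HEADER or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{line_no}: expected 3 tab-separated columns, got {len(parts)}"
                )
            protein, cls, raw_score = parts
            try:
                score = float(raw_score)
            except ValueError:
                raise ValueError(
                    f"{path}:{line_no}: non-numeric score {raw_score!r}"
                ) from None
            scores.setdefault(protein, {})[cls] = score
    return PredictionSet(scores)


# ---------------------------------------------------------------------- #
# CAFA submission format
# ---------------------------------------------------------------------- #


def write_cafa_submission(
    preds: PredictionSet,
    path: str,
    author: str,
    model_number: int = 1,
    keywords: str = "sequence properties",
    id_mapping: Optional[Mapping[str, str]] = None,
    min_report_score: float = 0.01,
) -> None:
    """CAFA-style submission: AUTHOR/MODEL/KEYWORDS header, rows of
    ``target GO-id score`` (2 decimals) and an END footer.  ``id_mapping``
    translates internal protein ids to challenge target ids."""
    id_mapping = dict(id_mapping or {})
    with open(path, "w") as fh:
        fh.write(f"AUTHOR {author}\n")
        fh.write(f"MODEL {model_number}\n")
        fh.write(f"KEYWORDS {keywords}.\n")
        for protein in preds.proteins:
            target = id_mapping.get(protein, protein)
            for cls in sorted(preds[protein]):
                score = preds[protein][cls]
                if score < min_report_score:
                    continue
                fh.write(f"{target}\t{cls}\t{min(score, 1.0):.2f}\n")
        fh.write("END\n")
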