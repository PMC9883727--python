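"""CAFA-style protein-centric evaluation: Fmax, Smin and AUPR.

For a benchmark of n proteins with true (ancestor-closed) annotation sets
T_i and predicted sets P_i(t) = {f : score > t} at threshold t:

* precision pr_i(t) = |P_i(t) ∩ T_i| / |P_i(t)|, averaged over the m(t)
  proteins with at least one prediction; recall rc_i(t) = |P_i(t) ∩ T_i| /
  |T_i|, averaged over all n proteins; Fmax is the maximum over the
  threshold grid {0.00, 0.01, ..., 1.00} of the harmonic mean of the two
  averages (thresholds where m(t) = 0 are skipped).
* remaining uncertainty ru(t) = mean over proteins of the summed
  information content of missed true classes T_i \\ P_i(t); misinformation
  mi(t) = mean summed IC of wrongly predicted classes P_i(t) \\ T_i; Smin
  is the minimum over thresholds of sqrt(ru² + mi²).
* AUPR is micro-averaged: all (protein, class) pairs over the benchmark
  proteins and the union of classes appearing in truth or predictions are
  pooled, ranked by score, and the precision–recall curve integrated by the
  trapezoidal rule.

Evaluation runs per sub-ontology after propagating both truth and
predictions under either the whole-ontology or the per-sub-ontology
(CAFA3) ancestor closure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import precision_recall_curve

from .containers import AnnotationCorpus, PredictionSet
from .ontology import (
    GeneOntology,
    ICTable,
    PER_SUBONTOLOGY,
    WHOLE_ONTOLOGY,
    propagate,
)

logger = logging.getLogger(__name__)

#: The standard CAFA threshold grid, step 0.01.
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.001, 0.01), 2))


def _matrices(
    preds: PredictionSet, truth: AnnotationCorpus
) -> Tuple[List[str], List[str], np.ndarray, np.ndarray]:
    """Benchmark-aligned score and truth matrices.

    Rows: proteins in the truth corpus (predictions for other proteins are
    ignored, CAFA convention).  Columns: classes appearing in truth or in
    the benchmark proteins' predictions.
    """
    if not truth.propagated:
        raise ValueError("evaluation requires a propagated truth corpus")
    if len(truth) == 0:
        raise ValueError("truth corpus is empty")
    proteins = truth.proteins
    class_set = set(truth.classes())
    for p in proteins:
        if p in preds:
            class_set |= set(preds[p])
    classes = sorted(class_set)
    col = {c: j for j, c in enumerate(classes)}
    s = np.zeros((len(proteins), len(classes)))
    t = np.zeros((len(proteins), len(classes)), dtype=bool)
    for i, p in enumerate(proteins):
        for c in truth[p]:
            t[i, col[c]] = True
        if p in preds:
            for c, score in preds[p].items():
                s[i, col[c]] = score
    return proteins, classes, s, t


def fmax(
    preds: PredictionSet,
    truth: AnnotationCorpus,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> Tuple[float, float, Dict[str, np.ndarray]]:
    """Protein-centric Fmax over the threshold grid.

    Returns (fmax, threshold attaining it, per-threshold curves).  Curves
    hold AvgPr(t) (NaN where m(t)=0), AvgRc(t), m(t) and F(t).
    """
    _, _, s, t = _matrices(preds, truth)
    n = s.shape[0]
    n_true = t.sum(axis=1)  # |T_i| >= 1 by corpus invariant
    ts = np.asarray(thresholds, dtype=float)
    avg_pr = np.full(len(ts), np.nan)
    avg_rc = np.zeros(len(ts))
    m_arr = np.zeros(len(ts), dtype=int)
    f_arr = np.zeros(len(ts))
    best_f, best_t = 0.0, float("nan")
    any_valid = False
    for k, thr in enumerate(ts):
        p = s > thr
        tp = (p & t).sum(axis=1)
        n_pred = p.sum(axis=1)
        has_pred = n_pred > 0
        m = int(has_pred.sum())
        m_arr[k] = m
        avg_rc[k] = float(np.mean(tp / n_true))
        if m == 0:
            continue
        any_valid = True
        avg_pr[k] = float(np.mean(tp[has_pred] / n_pred[has_pred]))
        denom = avg_pr[k] + avg_rc[k]
        f_arr[k] = 2.0 * avg_pr[k] * avg_rc[k] / denom if denom > 0 else 0.0
        if f_arr[k] > best_f:
            best_f, best_t = f_arr[k], float(thr)
    if not any_valid:
        warnings.warn("no threshold yields any prediction; Fmax defined as 0")
        return 0.0, 0.0, {
            "thresholds": ts, "avg_pr": avg_pr, "avg_rc": avg_rc,
            "m": m_arr, "f": f_arr,
        }
    if np.isnan(best_t):  # best F is exactly 0 at every valid threshold
        best_t = float(ts[m_arr > 0][0])
    curves = {"thresholds": ts, "avg_pr": avg_pr, "avg_rc": avg_rc, "m": m_arr, "f": f_arr}
    return best_f, best_t, curves


def smin(
    preds: PredictionSet,
    truth: AnnotationCorpus,
    ic: ICTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> Tuple[float, float, Dict[str, np.ndarray]]:
    """Minimum semantic distance sqrt(ru(t)² + mi(t)²) over the grid."""
    _, classes, s, t = _matrices(preds, truth)
    missing = [c for c in classes if c not in ic]
    if missing:
        raise ValueError(f"classes missing from the IC table: {missing[:10]}")
    ic_vec = np.array([ic[c] for c in classes])
    ts = np.asarray(thresholds, dtype=float)
    ru = np.zeros(len(ts))
    mi = np.zeros(len(ts))
    for k, thr in enumerate(ts):
        p = s > thr
        ru[k] = float(((t & ~p) * ic_vec).sum(axis=1).mean())
        mi[k] = float(((p & ~t) * ic_vec).sum(axis=1).mean())
    dist = np.sqrt(ru**2 + mi**2)
    k_best = int(np.argmin(dist))
    curves = {"thresholds": ts, "ru": ru, "mi": mi, "distance": dist}
    return float(dist[k_best]), float(ts[k_best]), curves


def aupr(preds: PredictionSet, truth: AnnotationCorpus) -> float:
    """Micro-averaged area under the precision–recall curve.

    The pair universe is benchmark proteins × (classes in truth or in their
    predictions); unscored pairs enter with score 0.  Trapezoidal rule at
    every distinct score.
    """
    _, _, s, t = _matrices(preds, truth)
    y_true = t.ravel().astype(int)
    y_score = s.ravel()
    if y_true.sum() == 0:
        raise ValueError("truth corpus has no positive (protein, class) pairs")
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    # recall is decreasing in sklearn's output ordering
    return float(-np.trapezoid(precision, recall))


def propagate_scores(
    preds: PredictionSet, go: GeneOntology, mode: str = WHOLE_ONTOLOGY
) -> PredictionSet:
    """Ancestor-close a prediction set: every ancestor of a predicted class
    receives at least that class's score (max over descendants and itself).
    Classes unknown to the ontology are skipped with a warning."""
    out: Dict[str, Dict[str, float]] = {}
    for protein in preds.proteins:
        table: Dict[str, float] = {}
        for cls, score in preds[protein].items():
            try:
                primary = go.resolve(cls)
            except (KeyError, ValueError):
                logger.warning("skipping prediction for unknown class %s", cls)
                continue
            for c in (primary, *go.ancestors(primary, mode)):
                if score > table.get(c, 0.0):
                    table[c] = score
        out[protein] = table
    return PredictionSet(out)


@dataclass
class EvaluationResult:
    """Per-sub-ontology evaluation summary."""

    namespace: str
    n: int
    fmax: float
    t_opt: float
    aupr: float
    smin: Optional[float] = None
    t_smin: Optional[float] = None
    curves: Dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> str:
        parts = [
            f"{self.namespace}: n={self.n}",
            f"Fmax={self.fmax:.3f} (t={self.t_opt:.2f})",
            f"AUPR={self.aupr:.3f}",
        ]
        if self.smin is not None:
            parts.append(f"Smin={self.smin:.3f} (t={self.t_smin:.2f})")
        return "  ".join(parts)


def evaluate(
    preds: PredictionSet,
    truth: AnnotationCorpus,
    go: GeneOntology,
    ic: Optional[ICTable] = None,
    mode: str = WHOLE_ONTOLOGY,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    namespaces: Iterable[str] = ("MFO", "BPO", "CCO"),
) -> Dict[str, EvaluationResult]:
    """Propagate truth and predictions under ``mode``, split both by
    namespace, and compute Fmax / Smin / AUPR per sub-ontology.

    Sub-ontologies with no benchmark annotations are omitted from the
    result.  Smin is reported only when an IC table is supplied.
    """
    if mode not in (WHOLE_ONTOLOGY, PER_SUBONTOLOGY):
        raise ValueError(f"unknown mode {mode!r}")
    truth_prop = propagate(truth, go, mode)
    preds_prop = propagate_scores(preds, go, mode)
    results: Dict[str, EvaluationResult] = {}
    for ns in namespaces:
        ns_classes = frozenset(go.classes_in_namespace(ns))
        truth_ns = truth_prop.restrict_classes(ns_classes)
        if len(truth_ns) == 0:
            continue
        preds_ns = preds_prop.restrict_classes(ns_classes)
        f, t_opt, f_curves = fmax(preds_ns, truth_ns, thresholds)
        a = aupr(preds_ns, truth_ns)
        res = EvaluationResult(
            namespace=ns, n=len(truth_ns), fmax=f, t_opt=t_opt, aupr=a,
            curves=f_curves,
        )
        if ic is not None:
            s, t_s, s_curves = smin(preds_ns, truth_ns, ic, thresholds)
            res.smin, res.t_smin = s, t_s
            res.curves.update(s_curves)
        results[ns] = res
    return results
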