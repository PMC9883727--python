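"""Brute-force reference implementations of the protein-centric metrics.

Direct, unoptimized translations of the metric definitions — dictionary and
set arithmetic, explicit loops over proteins, classes and thresholds — kept
deliberately independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np

THRESHOLDS = [round(0.01 * k, 2) for k in range(101)]


def predicted_set(scores: Mapping[str, float], t: float) -> Set[str]:
    return {f for f, s in scores.items() if s > t}


def brute_fmax(
    preds: Mapping[str, Mapping[str, float]],
    truth: Mapping[str, Set[str]],
    thresholds: Sequence[float] = THRESHOLDS,
) -> float:
    proteins = sorted(truth)
    n = len(proteins)
    best = 0.0
    for t in thresholds:
        m = 0
        pr_sum = 0.0
        rc_sum = 0.0
        for p in proteins:
            pset = predicted_set(preds.get(p, {}), t)
            tset = truth[p]
            rc_sum += len(pset & tset) / len(tset)
            if pset:
                m += 1
                pr_sum += len(pset & tset) / len(pset)
        if m == 0:
            continue
        avg_pr = pr_sum / m
        avg_rc = rc_sum / n
        if avg_pr + avg_rc > 0:
            best = max(best, 2 * avg_pr * avg_rc / (avg_pr + avg_rc))
    return best


def brute_smin(
    preds: Mapping[str, Mapping[str, float]],
    truth: Mapping[str, Set[str]],
    ic: Mapping[str, float],
    thresholds: Sequence[float] = THRESHOLDS,
) -> float:
    proteins = sorted(truth)
    n = len(proteins)
    best = math.inf
    for t in thresholds:
        ru = 0.0
        mi = 0.0
        for p in proteins:
            pset = predicted_set(preds.get(p, {}), t)
            tset = truth[p]
            ru += sum(ic[c] for c in tset - pset)
            mi += sum(ic[c] for c in pset - tset)
        ru /= n
        mi /= n
        best = min(best, math.sqrt(ru * ru + mi * mi))
    return best


def brute_aupr(
    preds: Mapping[str, Mapping[str, float]],
    truth: Mapping[str, Set[str]],
) -> float:
    proteins = sorted(truth)
    classes: Set[str] = set()
    for p in proteins:
        classes |= truth[p]
        classes |= set(preds.get(p, {}))
    pairs = [
        (1 if c in truth[p] else 0, preds.get(p, {}).get(c, 0.0))
        for p in proteins
        for c in sorted(classes)
    ]
    n_pos = sum(y for y, _ in pairs)
    points = [(0.0, 1.0)]  # (recall, precision) anchor
    for s in sorted({sc for _, sc in pairs}, reverse=True):
        tp = sum(y for y, sc in pairs if sc >= s)
        n_pred = sum(1 for _, sc in pairs if sc >= s)
        points.append((tp / n_pos, tp / n_pred))
    area = 0.0
    for (r1, p1), (r2, p2) in zip(points, points[1:]):
        area += (r2 - r1) * (p1 + p2) / 2.0
    return area


def random_instance(
    rng: np.random.Generator,
    max_proteins: int = 20,
    max_classes: int = 30,
) -> Tuple[Dict[str, Set[str]], Dict[str, Dict[str, float]], Dict[str, float]]:
    """A random benchmark: truth sets, prediction scores, IC values."""
    n = int(rng.integers(2, max_proteins + 1))
    c = int(rng.integers(2, max_classes + 1))
    classes = [f"GO:{i:07d}" for i in range(1, c + 1)]
    truth: Dict[str, Set[str]] = {}
    preds: Dict[str, Dict[str, float]] = {}
    for i in range(n):
        p = f"P{i + 1}"
        k = int(rng.integers(1, c + 1))
        truth[p] = set(
            classes[int(j)] for j in rng.choice(c, size=k, replace=False)
        )
        k_pred = int(rng.integers(0, c + 1))
        chosen = rng.choice(c, size=k_pred, replace=False)
        preds[p] = {
            classes[int(j)]: float(round(rng.random(), 3)) for j in chosen
        }
    ic = {cl: float(rng.random() * 3.0) for cl in classes}
    return truth, preds, ic
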