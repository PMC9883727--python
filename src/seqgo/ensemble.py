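"""Weighted-sum ensemble of homology-transfer and CNN predictions.

The final score is S = α · S_similarity + (1 − α) · S_cnn, with a separate
weight α per sub-ontology (defaults tuned on validation data at full scale:
MFO 0.55, BPO 0.59, CCO 0.46).  A class scored by only one component
contributes 0 for the other — except that a protein with no similarity
hits at all keeps its CNN scores unscaled, so novel proteins without
annotated homologs are not penalized by the (1 − α) shrinkage.  α is tuned
per sub-ontology by maximizing validation Fmax on a grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

from .containers import AnnotationCorpus, PredictionSet
from .evaluation import fmax
from .ontology import GeneOntology

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = {"MFO": 0.55, "BPO": 0.59, "CCO": 0.46}


@dataclass
class AlphaConfig:
    """Per-sub-ontology mixing weight α ∈ [0, 1] and the tuning grid step."""

    alpha: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHAS))
    grid_step: float = 0.01

    def __post_init__(self) -> None:
        for ns, a in self.alpha.items():
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"alpha for {ns} outside [0, 1]: {a}")

    def grid(self) -> np.ndarray:
        n = int(round(1.0 / self.grid_step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 10)


def combine(
    diamond: PredictionSet,
    cnn: PredictionSet,
    alpha_cfg: AlphaConfig,
    go: GeneOntology,
    strict: bool = False,
) -> PredictionSet:
    """Weighted sum per protein and class, using the α of each class's
    namespace.

    A protein absent from the similarity predictions keeps its CNN scores
    unscaled unless ``strict`` (pure weighted sum with missing scores as 0).
    """
    out: Dict[str, Dict[str, float]] = {}
    proteins = set(diamond.scores) | set(cnn.scores)
    for protein in sorted(proteins):
        d = diamond.scores.get(protein)
        c = cnn.scores.get(protein, {})
        if d is None and not strict:
            out[protein] = dict(c)  # no-hit fallback: CNN passes through
            continue
        d = d or {}
        table: Dict[str, float] = {}
        for cls in set(d) | set(c):
            ns = go.namespace_of(cls)
            a = alpha_cfg.alpha[ns]
            score = a * d.get(cls, 0.0) + (1.0 - a) * c.get(cls, 0.0)
            table[cls] = min(1.0, max(0.0, score))
        out[protein] = table
    return PredictionSet(out)


def tune_alpha(
    diamond_val: PredictionSet,
    cnn_val: PredictionSet,
    truth: AnnotationCorpus,
    go: GeneOntology,
    grid_step: float = 0.01,
    strict: bool = False,
) -> Tuple[AlphaConfig, Dict[str, np.ndarray]]:
    """Per-sub-ontology α maximizing validation Fmax over the grid
    {0, grid_step, ..., 1}; ties broken toward the smaller α.

    Returns the tuned :class:`AlphaConfig` and, per namespace, the full
    α → Fmax curve (rows of (alpha, fmax)).
    """
    if not truth.propagated:
        raise ValueError("tune_alpha requires a propagated truth corpus")
    if len(truth) == 0:
        raise ValueError("validation truth corpus is empty")
    cfg = AlphaConfig(grid_step=grid_step)
    grid = cfg.grid()
    curves: Dict[str, np.ndarray] = {}
    tuned: Dict[str, float] = {}
    for ns in ("MFO", "BPO", "CCO"):
        ns_classes = frozenset(go.classes_in_namespace(ns))
        truth_ns = truth.restrict_classes(ns_classes)
        if len(truth_ns) == 0:
            tuned[ns] = DEFAULT_ALPHAS[ns]
            logger.warning("no validation truth in %s; keeping default alpha", ns)
            continue
        d_ns = diamond_val.restrict_classes(ns_classes)
        c_ns = cnn_val.restrict_classes(ns_classes)
        fvals = np.zeros(len(grid))
        for k, a in enumerate(grid):
            a_cfg = AlphaConfig(alpha={n2: float(a) for n2 in ("MFO", "BPO", "CCO")})
            mix = combine(d_ns, c_ns, a_cfg, go, strict=strict)
            fvals[k], _, _ = fmax(mix, truth_ns)
        best = int(np.argmax(fvals))  # argmax takes the first (smallest α) on ties
        tuned[ns] = float(grid[best])
        curves[ns] = np.column_stack([grid, fvals])
    return AlphaConfig(alpha=tuned, grid_step=grid_step), curves
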