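"""End-to-end synthetic benchmark: generate data, train the CNN, run the
homology baselines, tune the ensemble weight on a validation split, and
evaluate everything on a held-out test split.

Problem sizes are desk-scale on purpose: the default generator produces 500
proteins over a 45-term ontology, split 360/40/100 into CNN-training,
ensemble-validation and test proteins.  The CNN for this experiment uses
filter lengths (8, 16) with 64 filters each — ample for planted motifs of
8–24 residues — so the whole run takes seconds on one CPU.  The full-scale
default architecture (16 filter lengths x 512 filters) is exercised
analytically elsewhere; its training is GPU territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .baselines import diamond_score, naive_scores
from .cnn import CNNConfig, CNNModel, build_model, train
from .containers import AnnotationCorpus, PredictionSet, SimilarityTable
from .ensemble import AlphaConfig, combine, tune_alpha
from .evaluation import evaluate, fmax
from .ontology import compute_ic, select_classes
from .synthetic import (
    SyntheticDataset,
    SyntheticSpec,
    motif_recovery_rate,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

#: Training configuration for the desk-scale motif-recovery experiment.
BENCHMARK_CNN_CONFIG = CNNConfig(
    filter_lengths=(8, 16),
    filters_per_length=64,
    learning_rate=1e-3,
    batch_size=32,
    max_epochs=100,
    patience=6,
)


@dataclass
class BenchmarkResult:
    """Everything the synthetic end-to-end run produces."""

    dataset: SyntheticDataset
    terms: List[str]
    model: CNNModel
    val_ids: List[str]
    cnn_train_ids: List[str]
    alpha: AlphaConfig
    alpha_curves: Dict[str, np.ndarray]
    # held-out test metrics
    cnn_test_fmax: float  # against truth restricted to the model's classes
    motif_recovery: float
    test_fmax: Dict[str, float]  # predictor name -> overall test Fmax
    test_smin: Dict[str, float]
    test_aupr: Dict[str, float]
    val_fmax: Dict[str, Dict[str, float]]  # predictor -> namespace -> Fmax
    val_fmax_gain: float  # min over namespaces of ensemble - best component
    n_test: int
    n_val: int


def _restrict(preds: PredictionSet, proteins) -> PredictionSet:
    keep = frozenset(proteins)
    return PredictionSet({p: preds[p] for p in preds.proteins if p in keep})


def _subtable(table: SimilarityTable, queries, subjects) -> SimilarityTable:
    queries = frozenset(queries)
    subjects = frozenset(subjects)
    return SimilarityTable(
        {
            q: [h for h in table[q] if h.subject in subjects]
            for q in table.queries
            if q in queries
        }
    )


def run_synthetic_benchmark(
    seed: int = 7,
    spec: Optional[SyntheticSpec] = None,
    cnn_config: Optional[CNNConfig] = None,
    min_count: int = 50,
    val_fraction: float = 0.1,
) -> BenchmarkResult:
    """Run the full pipeline on generated data.

    ``seed`` drives the generator, the splits and the model initialization.
    """
    if spec is None:
        spec = SyntheticSpec(seed=seed)
    dataset = simulate_dataset(spec)
    go, truth = dataset.go, dataset.truth

    # carve an ensemble-validation split out of the training proteins
    rng = np.random.default_rng([seed, 101])
    train_ids = list(dataset.train_ids)
    perm = rng.permutation(len(train_ids))
    n_val = max(1, int(round(val_fraction * len(train_ids))))
    val_ids = sorted(train_ids[int(i)] for i in perm[:n_val])
    cnn_train_ids = sorted(train_ids[int(i)] for i in perm[n_val:])

    train_truth = truth.restrict_proteins(cnn_train_ids)
    terms = select_classes(train_truth, min_count=min_count)
    if not terms:
        raise ValueError("no class reaches the selection threshold")

    config = cnn_config or BENCHMARK_CNN_CONFIG
    config = type(config)(**{**config.__dict__, "seed": seed})
    model = build_model(config, terms)
    by_id = dataset.records_by_id
    train(model, [by_id[p] for p in cnn_train_ids], train_truth)

    # component predictions
    cnn_val = model.predict_records([by_id[p] for p in val_ids])
    cnn_test = model.predict_records([by_id[p] for p in dataset.test_ids])
    diamond_val = diamond_score(
        _subtable(dataset.similarity, val_ids, cnn_train_ids), train_truth
    )
    diamond_test = diamond_score(
        _subtable(dataset.similarity, dataset.test_ids, cnn_train_ids), train_truth
    )
    naive_test = naive_scores(train_truth, dataset.test_ids)

    # tune the ensemble weight on the validation split
    val_truth = truth.restrict_proteins(val_ids)
    alpha, curves = tune_alpha(diamond_val, cnn_val, val_truth, go)
    ens_val = combine(diamond_val, cnn_val, alpha, go)
    ens_test = combine(diamond_test, cnn_test, alpha, go)

    # held-out metrics
    test_truth = truth.restrict_proteins(dataset.test_ids)
    cnn_universe_truth = test_truth.restrict_classes(terms)
    cnn_test_fmax, _, _ = fmax(cnn_test, cnn_universe_truth)
    recovery = motif_recovery_rate(model, dataset)

    ic = compute_ic(train_truth, go)
    predictors = {
        "naive": naive_test,
        "diamond": diamond_test,
        "cnn": cnn_test,
        "ensemble": ens_test,
    }
    test_fmax: Dict[str, float] = {}
    test_smin: Dict[str, float] = {}
    test_aupr: Dict[str, float] = {}
    from .evaluation import aupr as aupr_fn, smin as smin_fn

    for name, preds in predictors.items():
        f, _, _ = fmax(preds, test_truth)
        s, _, _ = smin_fn(preds, test_truth, ic)
        test_fmax[name] = f
        test_smin[name] = s
        test_aupr[name] = aupr_fn(preds, test_truth)

    # validation comparison per sub-ontology (alpha is tuned per namespace,
    # so that is the granularity at which the ensemble dominates components)
    val_fmax: Dict[str, Dict[str, float]] = {
        "diamond": {}, "cnn": {}, "ensemble": {}
    }
    gains: List[float] = []
    for ns in ("MFO", "BPO", "CCO"):
        ns_classes = frozenset(go.classes_in_namespace(ns))
        val_truth_ns = val_truth.restrict_classes(ns_classes)
        if len(val_truth_ns) == 0:
            continue
        for name, preds in {
            "diamond": diamond_val, "cnn": cnn_val, "ensemble": ens_val
        }.items():
            f, _, _ = fmax(preds.restrict_classes(ns_classes), val_truth_ns)
            val_fmax[name][ns] = f
        gains.append(
            val_fmax["ensemble"][ns]
            - max(val_fmax["diamond"][ns], val_fmax["cnn"][ns])
        )

    return BenchmarkResult(
        dataset=dataset,
        terms=terms,
        model=model,
        val_ids=val_ids,
        cnn_train_ids=cnn_train_ids,
        alpha=alpha,
        alpha_curves=curves,
        cnn_test_fmax=cnn_test_fmax,
        motif_recovery=recovery,
        test_fmax=test_fmax,
        test_smin=test_smin,
        test_aupr=test_aupr,
        val_fmax=val_fmax,
        val_fmax_gain=min(gains),
        n_test=len(dataset.test_ids),
        n_val=len(val_ids),
    )
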