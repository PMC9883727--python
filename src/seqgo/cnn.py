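"""Convolutional sequence-motif classifier.

The model scans a one-hot encoded amino-acid sequence (21 rows: 20 standard
residues plus one "unknown" row; fixed input width, zero-padded) with banks
of 1-D convolutional filters of several lengths.  Each filter produces an
activation profile over positions; global max pooling keeps only the single
best match per filter, so a filter behaves as a soft motif detector: it
fires if its motif occurs anywhere in the sequence.  The pooled feature
vector (|filter lengths| x filters per length) feeds a flat fully connected
layer with sigmoid outputs, one per GO class — a multi-label classifier
trained with binary cross-entropy and Adam, early-stopped on a held-out
validation split.

The convolution layers use no nonlinearity and the classifier is flat (no
hierarchy); sequences longer than the input width are split into chunks
scored independently and merged by elementwise maximum, which matches the
global-max-pooling semantics (a motif in any chunk should fire).

Implemented directly in numpy: im2col convolution, manual backprop through
the max-pooling argmax, Adam updates.  Training is bit-reproducible for a
fixed (seed, data, config).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import AnnotationCorpus, PredictionSet, SequenceRecord

logger = logging.getLogger(__name__)

#: Canonical alphabetical order of the 20 standard amino acids; every other
#: letter (B, J, O, U, X, Z, *, ...) maps to the 21st "unknown" row.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
N_SYMBOLS = 21
UNKNOWN_INDEX = 20

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters.

    Defaults are the full-scale architecture: filter lengths 8, 16, ..., 128
    with 512 filters each (pooled feature vector 16 x 512 = 8192), one dense
    layer, binary cross-entropy, Adam with learning rate 3e-4, input width
    2000 residues.
    """

    alphabet: str = AA_ALPHABET
    max_len: int = 2000
    filter_lengths: Tuple[int, ...] = tuple(range(8, 129, 8))
    filters_per_length: int = 512
    dense_depth: int = 1
    dense_units: int = 512  # width of intermediate dense layers (depth > 1)
    learning_rate: float = 3e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 6
    validation_fraction: float = 0.1
    chunk_overlap: bool = False  # overlap chunks by (longest filter - 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.alphabet) != 20 or len(set(self.alphabet)) != 20:
            raise ValueError("alphabet must be 20 distinct standard residues")
        fl = self.filter_lengths
        if not fl or any(b <= a for a, b in zip(fl, fl[1:])):
            raise ValueError("filter_lengths must be strictly increasing")
        if fl[-1] > self.max_len:
            raise ValueError("filter lengths must not exceed max_len")
        if self.dense_depth < 1:
            raise ValueError("dense_depth must be >= 1")

    @property
    def feature_dim(self) -> int:
        """Pooled feature vector length: |filter_lengths| x filters_per_length."""
        return len(self.filter_lengths) * self.filters_per_length


#: The hyperparameter search grid: filter-length sets stopping at
#: 32/64/128/256/512, filter counts 32..512, dense depth 1..3 — 75 combos.
def hyperparameter_grid() -> List[CNNConfig]:
    grid: List[CNNConfig] = []
    for stop in (32, 64, 128, 256, 512):
        lengths = tuple(range(8, stop + 1, 8))
        for n_filters in (32, 64, 128, 256, 512):
            for depth in (1, 2, 3):
                grid.append(
                    CNNConfig(
                        max_len=2000,
                        filter_lengths=lengths,
                        filters_per_length=n_filters,
                        dense_depth=depth,
                    )
                )
    return grid


# ---------------------------------------------------------------------- #
# Encoding and chunking
# ---------------------------------------------------------------------- #


def encode_sequence(
    seq: str, config: CNNConfig, length: Optional[int] = None
) -> np.ndarray:
    """One-hot encode to a 21 x length matrix (length defaults to max_len).

    Column j holds a single 1 at the row of residue j; non-standard letters
    hit the unknown row; columns beyond len(seq) are all zero.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if length is None:
        length = config.max_len
    if len(seq) > length:
        raise ValueError(
            f"sequence length {len(seq)} exceeds encoding width {length}; "
            "use chunk_sequence first"
        )
    out = np.zeros((N_SYMBOLS, length), dtype=np.float32)
    idx = config.alphabet
    index = _AA_INDEX if idx == AA_ALPHABET else {aa: i for i, aa in enumerate(idx)}
    rows = [index.get(aa, UNKNOWN_INDEX) for aa in seq.upper()]
    out[rows, np.arange(len(seq))] = 1.0
    return out


def decode_matrix(mat: np.ndarray, config: CNNConfig) -> str:
    """Inverse of encode_sequence up to ambiguity collapse (unknown -> 'X')."""
    symbols = config.alphabet + "X"
    cols = np.flatnonzero(mat.sum(axis=0) > 0)
    return "".join(symbols[int(mat[:, j].argmax())] for j in cols)


def chunk_sequence(seq: str, config: CNNConfig) -> List[str]:
    """Split into windows of at most max_len residues.

    Non-overlapping by default (concatenation of chunks == seq); with
    ``chunk_overlap`` consecutive windows overlap by (longest filter - 1)
    residues so boundary-spanning motifs are not missed.
    """
    n = len(seq)
    if n <= config.max_len:
        return [seq]
    if config.chunk_overlap:
        step = config.max_len - (config.filter_lengths[-1] - 1)
    else:
        step = config.max_len
    chunks = []
    for start in range(0, n, step):
        chunk = seq[start : start + config.max_len]
        if chunk:
            chunks.append(chunk)
        if start + config.max_len >= n:
            break
    return chunks


# ---------------------------------------------------------------------- #
# Model
# ---------------------------------------------------------------------- #


@dataclass
class FilterActivation:
    """Best activation of one convolutional filter on one sequence."""

    index: int  # global filter index in feature-vector order
    length: int
    score: float
    position: int  # argmax position (first occurrence on ties)
    window: str  # seq[position : position + length]


class CNNModel:
    """A (possibly trained) convolutional motif classifier.

    Attributes
    ----------
    config : CNNConfig
    terms : ordered GO class ids; output coordinate j scores terms[j].
    params : name -> numpy array weight store.
    history : per-epoch train/validation loss lists.
    """

    def __init__(self, config: CNNConfig, terms: Sequence[str]) -> None:
        if not terms:
            raise ValueError("terms must be non-empty")
        self.config = config
        self.terms: Tuple[str, ...] = tuple(terms)
        self.history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
        self.trained = False
        self.params: Dict[str, np.ndarray] = {}
        self._init_params()

    # -------------------------- initialization ------------------------- #

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        f = cfg.filters_per_length
        for L in cfg.filter_lengths:
            fan_in = N_SYMBOLS * L
            limit = np.sqrt(6.0 / (fan_in + f))
            self.params[f"conv_w_{L}"] = rng.uniform(
                -limit, limit, size=(f, N_SYMBOLS, L)
            ).astype(np.float32)
            self.params[f"conv_b_{L}"] = np.zeros(f, dtype=np.float32)
        widths = [cfg.feature_dim]
        widths += [cfg.dense_units] * (cfg.dense_depth - 1)
        widths.append(len(self.terms))
        for i, (w_in, w_out) in enumerate(zip(widths, widths[1:])):
            limit = np.sqrt(6.0 / (w_in + w_out))
            self.params[f"dense_w_{i}"] = rng.uniform(
                -limit, limit, size=(w_out, w_in)
            ).astype(np.float32)
            self.params[f"dense_b_{i}"] = np.zeros(w_out, dtype=np.float32)

    # ---------------------------- forward ------------------------------ #

    def _conv_forward(
        self, x: np.ndarray, keep_cache: bool = False
    ) -> Tuple[np.ndarray, Dict[int, np.ndarray], Dict[int, np.ndarray]]:
        """Pooled features for a one-hot batch x of shape (N, 21, T).

        Returns (features (N, feature_dim), argmax per length (N, f),
        im2col cache per length — only when keep_cache).
        """
        cfg = self.config
        n = x.shape[0]
        feats: List[np.ndarray] = []
        argmaxes: Dict[int, np.ndarray] = {}
        caches: Dict[int, np.ndarray] = {}
        for L in cfg.filter_lengths:
            t = x.shape[2]
            if t < L:
                raise ValueError(f"input width {t} shorter than filter length {L}")
            w = self.params[f"conv_w_{L}"].reshape(cfg.filters_per_length, -1)
            b = self.params[f"conv_b_{L}"]
            windows = sliding_window_view(x, L, axis=2)  # (N, 21, P, L)
            cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
                n, -1, N_SYMBOLS * L
            )  # (N, P, 21L)
            act = cols @ w.T + b  # (N, P, f)
            am = act.argmax(axis=1)  # (N, f); numpy argmax takes first on ties
            feats.append(np.take_along_axis(act, am[:, None, :], axis=1)[:, 0, :])
            argmaxes[L] = am
            if keep_cache:
                caches[L] = cols
        return np.concatenate(feats, axis=1), argmaxes, caches

    def _dense_forward(
        self, feats: np.ndarray
    ) -> Tuple[np.ndarray, List[np.ndarray]]:
        """Sigmoid outputs and the list of layer inputs (for backprop)."""
        cfg = self.config
        h = feats
        layer_inputs = [h]
        for i in range(cfg.dense_depth - 1):
            z = h @ self.params[f"dense_w_{i}"].T + self.params[f"dense_b_{i}"]
            h = np.maximum(z, 0.0)  # ReLU on intermediate layers
            layer_inputs.append(h)
        i = cfg.dense_depth - 1
        logits = h @ self.params[f"dense_w_{i}"].T + self.params[f"dense_b_{i}"]
        probs = 1.0 / (1.0 + np.exp(-logits))
        return probs, layer_inputs

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, |terms|) for a one-hot batch."""
        feats, _, _ = self._conv_forward(x)
        probs, _ = self._dense_forward(feats)
        return probs

    # --------------------------- prediction ---------------------------- #

    def _encoding_width(self, max_seq_len: int) -> int:
        # Wide enough that every shorter sequence keeps at least one
        # all-zero window per filter bank, making scores independent of
        # batch composition (padding invariance).
        return min(self.config.max_len, max_seq_len + self.config.filter_lengths[-1])

    def predict_records(
        self,
        records: Sequence[SequenceRecord],
        batch_size: int = 64,
    ) -> PredictionSet:
        """Score sequences; inputs longer than max_len are chunked and the
        chunk scores merged by elementwise maximum."""
        cfg = self.config
        chunk_owner: List[str] = []
        chunks: List[str] = []
        for rec in records:
            for chunk in chunk_sequence(rec.sequence, cfg):
                if len(chunk) < cfg.filter_lengths[-1]:
                    # guard tiny trailing chunks: they are still scoreable
                    # because encoding width covers the longest filter
                    pass
                chunk_owner.append(rec.id)
                chunks.append(chunk)
        scores: Dict[str, np.ndarray] = {}
        order = np.argsort([len(c) for c in chunks], kind="stable")
        for start in range(0, len(chunks), batch_size):
            idx = order[start : start + batch_size]
            batch = [chunks[i] for i in idx]
            width = self._encoding_width(max(len(c) for c in batch))
            x = np.stack([encode_sequence(c, cfg, width) for c in batch])
            probs = self.forward(x)
            for row, i in enumerate(idx):
                pid = chunk_owner[i]
                if pid in scores:
                    scores[pid] = np.maximum(scores[pid], probs[row])
                else:
                    scores[pid] = probs[row].copy()
        return PredictionSet(
            {
                pid: {
                    term: float(np.clip(s[j], 0.0, 1.0))
                    for j, term in enumerate(self.terms)
                }
                for pid, s in scores.items()
            }
        )

    # ---------------------- filter interpretation ---------------------- #

    def filter_activations(self, seq: str) -> List[FilterActivation]:
        """Per-filter best-matching region of ``seq``.

        For each filter: the activation profile's argmax position (first
        occurrence on ties) over a valid convolution of the unpadded
        sequence, and the corresponding subsequence window.  Filters longer
        than the sequence are skipped; a sequence shorter than the smallest
        filter is an error.  Sorted by score descending.
        """
        cfg = self.config
        if len(seq) < cfg.filter_lengths[0]:
            raise ValueError(
                f"sequence length {len(seq)} is shorter than the smallest "
                f"filter ({cfg.filter_lengths[0]})"
            )
        x = encode_sequence(seq, cfg, length=len(seq))[None, :, :]
        records: List[FilterActivation] = []
        offset = 0
        for L in cfg.filter_lengths:
            if L > len(seq):
                offset += cfg.filters_per_length
                continue
            w = self.params[f"conv_w_{L}"].reshape(cfg.filters_per_length, -1)
            b = self.params[f"conv_b_{L}"]
            windows = sliding_window_view(x, L, axis=2)
            cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
                1, -1, N_SYMBOLS * L
            )
            act = (cols @ w.T + b)[0]  # (P, f)
            ams = act.argmax(axis=0)
            for f in range(cfg.filters_per_length):
                p = int(ams[f])
                records.append(
                    FilterActivation(
                        index=offset + f,
                        length=L,
                        score=float(act[p, f]),
                        position=p,
                        window=seq[p : p + L],
                    )
                )
            offset += cfg.filters_per_length
        records.sort(key=lambda r: (-r.score, r.index))
        return records

    def top_filters_for_class(self, cls: str, top: int = 10) -> List[int]:
        """Filters most associated with a class: the ``top`` global filter
        indices with the largest positive weight into the class's output
        unit.  Only meaningful for the flat (dense_depth == 1) classifier."""
        if self.config.dense_depth != 1:
            raise ValueError("filter-class association requires a flat classifier")
        j = self.terms.index(cls)
        w = self.params["dense_w_0"][j]  # (feature_dim,)
        return [int(i) for i in np.argsort(-w)[:top]]

    # -------------------------- serialization -------------------------- #

    def save(self, path_prefix: str) -> None:
        """Write weights to ``<prefix>.npz`` and a JSON sidecar with the
        config, terms and history so predictions are reconstructible."""
        np.savez(path_prefix + ".npz", **self.params)
        meta = {
            "config": asdict(self.config),
            "terms": list(self.terms),
            "history": self.history,
            "trained": self.trained,
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "CNNModel":
        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        cfg_dict = meta["config"]
        cfg_dict["filter_lengths"] = tuple(cfg_dict["filter_lengths"])
        config = CNNConfig(**cfg_dict)
        model = cls(config, meta["terms"])
        with np.load(path_prefix + ".npz") as data:
            model.params = {k: data[k] for k in data.files}
        model.history = meta["history"]
        model.trained = meta["trained"]
        return model


def build_model(config: CNNConfig, terms: Sequence[str]) -> CNNModel:
    """An untrained model with the given output classes."""
    return CNNModel(config, terms)


# ---------------------------------------------------------------------- #
# Training
# ---------------------------------------------------------------------- #

_EPS = 1e-7


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class _Adam:
    def __init__(self, params: Mapping[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _train_step(
    model: CNNModel, x: np.ndarray, y: np.ndarray, opt: _Adam
) -> float:
    """One forward/backward/update pass; returns the batch loss."""
    cfg = model.config
    n = x.shape[0]
    feats, argmaxes, caches = model._conv_forward(x, keep_cache=True)
    probs, layer_inputs = model._dense_forward(feats)
    loss = _bce(probs, y)

    grads: Dict[str, np.ndarray] = {}
    # output layer: d(BCE)/d(logits) for sigmoid outputs
    dz = (probs - y).astype(np.float32) / float(n * y.shape[1])
    for i in range(cfg.dense_depth - 1, -1, -1):
        h = layer_inputs[i]
        grads[f"dense_w_{i}"] = dz.T @ h
        grads[f"dense_b_{i}"] = dz.sum(axis=0)
        dh = dz @ model.params[f"dense_w_{i}"]
        if i > 0:
            dz = dh * (h > 0.0)  # ReLU gate of the layer below's output
    dfeat = dh  # gradient wrt pooled feature vector (N, feature_dim)

    f = cfg.filters_per_length
    for j, L in enumerate(cfg.filter_lengths):
        dblock = dfeat[:, j * f : (j + 1) * f]  # (N, f)
        am = argmaxes[L]  # (N, f)
        cols = caches[L]  # (N, P, 21L)
        gathered = cols[np.arange(n)[:, None], am, :]  # (N, f, 21L)
        gw = np.einsum("nf,nfd->fd", dblock, gathered)
        grads[f"conv_w_{L}"] = gw.reshape(f, N_SYMBOLS, L)
        grads[f"conv_b_{L}"] = dblock.sum(axis=0)

    opt.step(model.params, grads)
    return loss


def train(
    model: CNNModel,
    sequences: Sequence[SequenceRecord],
    labels: AnnotationCorpus,
    config: Optional[CNNConfig] = None,
) -> CNNModel:
    """Fit the classifier on labeled sequences.

    Multi-label targets are binary vectors over ``model.terms`` (1 iff the
    class is in the protein's propagated annotations).  A random
    ``validation_fraction`` of the training proteins (drawn from the config
    seed) is held out; training stops once the validation loss has not
    improved for ``patience`` epochs and the best-validation-loss weights
    are restored.  Bit-reproducible for fixed (seed, data, config).
    """
    cfg = config or model.config
    if not labels.propagated:
        raise ValueError("training labels must be a propagated corpus")
    seq_by_id = {rec.id: rec.sequence for rec in sequences}
    missing = [p for p in labels.records if p not in seq_by_id]
    if missing:
        raise ValueError(f"labeled proteins missing sequences: {missing[:5]} ...")

    proteins = sorted(labels.records)
    term_index = {t: j for j, t in enumerate(model.terms)}
    y_all = np.zeros((len(proteins), len(model.terms)), dtype=np.float32)
    for i, p in enumerate(proteins):
        for cls in labels[p]:
            j = term_index.get(cls)
            if j is not None:
                y_all[i, j] = 1.0
    dead = [model.terms[j] for j in np.flatnonzero(y_all.sum(axis=0) == 0)]
    if dead:
        logger.warning("%d terms have no positive labels, e.g. %s", len(dead), dead[:3])

    # training inputs longer than max_len: use the first chunk
    train_seqs: List[str] = []
    for p in proteins:
        s = seq_by_id[p]
        if len(s) > cfg.max_len:
            logger.warning("%s longer than max_len; training on the first chunk", p)
            s = s[: cfg.max_len]
        train_seqs.append(s)

    width = model._encoding_width(max(len(s) for s in train_seqs))
    x_all = np.stack([encode_sequence(s, cfg, width) for s in train_seqs])

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(proteins))
    n_val = max(1, int(round(cfg.validation_fraction * len(proteins))))
    if n_val >= len(proteins):
        raise ValueError("not enough proteins to hold out a validation split")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    opt = _Adam(model.params, cfg.learning_rate)
    best_val = np.inf
    best_params: Optional[Dict[str, np.ndarray]] = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(tr_idx)
        losses: List[float] = []
        weights: List[int] = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss = _train_step(model, x_all[idx], y_all[idx], opt)
            losses.append(loss)
            weights.append(len(idx))
        train_loss = float(np.average(losses, weights=weights))
        val_probs = model.forward(x_all[val_idx])
        val_loss = _bce(val_probs, y_all[val_idx])
        model.history["train_loss"].append(train_loss)
        model.history["val_loss"].append(val_loss)
        logger.info("epoch %d: train %.5f val %.5f", epoch, train_loss, val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(model.params)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    if best_params is not None:
        model.params = best_params
    model.trained = True
    return model


def predict(model: CNNModel, sequences: Sequence[SequenceRecord]) -> PredictionSet:
    """Module-level convenience for :meth:`CNNModel.predict_records`."""
    return model.predict_records(sequences)


def filter_activations(model: CNNModel, seq: str) -> List[FilterActivation]:
    """Module-level convenience for :meth:`CNNModel.filter_activations`."""
    return model.filter_activations(seq)
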