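"""The convolutional motif classifier: encoding, chunking, architecture
arithmetic, training behaviour, prediction invariances and filter
extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqgo.cnn import (
    AA_ALPHABET,
    CNNConfig,
    UNKNOWN_INDEX,
    build_model,
    chunk_sequence,
    decode_matrix,
    encode_sequence,
    hyperparameter_grid,
    train,
)
from seqgo.containers import AnnotationCorpus, SequenceRecord
from seqgo.ontology import propagate, select_classes
from seqgo.synthetic import SyntheticSpec, simulate_dataset

SMALL = CNNConfig(
    max_len=64, filter_lengths=(4, 8), filters_per_length=6, seed=3,
    batch_size=8, max_epochs=5, patience=2,
)


class TestEncoding:
    def test_single_residue(self):
        mat = encode_sequence("A", SMALL)
        assert mat.shape == (21, 64)
        assert mat[0, 0] == 1.0
        assert mat.sum() == 1.0

    def test_ambiguous_residues_hit_unknown_row(self):
        for letter in "XBJOUZ*":
            mat = encode_sequence(letter, SMALL)
            assert mat[UNKNOWN_INDEX, 0] == 1.0

    def test_column_sums_one_then_zero(self):
        seq = "MKVLW"
        mat = encode_sequence(seq, SMALL)
        sums = mat.sum(axis=0)
        assert np.all(sums[: len(seq)] == 1.0)
        assert np.all(sums[len(seq):] == 0.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_sequence("", SMALL)

    def test_too_long_rejected(self):
        with pytest.raises(ValueError, match="chunk"):
            encode_sequence("A" * 65, SMALL)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.text(alphabet=AA_ALPHABET + "XBZ", min_size=1, max_size=60))
    def test_decode_recovers_ambiguity_collapsed_sequence(self, seq):
        mat = encode_sequence(seq, SMALL)
        expected = "".join(c if c in AA_ALPHABET else "X" for c in seq)
        assert decode_matrix(mat, SMALL) == expected


class TestChunking:
    @pytest.mark.parametrize(
        "length,expected",
        [(1500, [2000]), (2000, [2000]), (4500, [2000, 2000, 500])],
        ids=["short", "boundary", "long"],
    )
    def test_window_lengths(self, length, expected):
        cfg = CNNConfig()
        chunks = chunk_sequence("A" * length, cfg)
        assert [len(c) for c in chunks] == [min(length, e) for e in expected]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=1, max_value=500))
    def test_concatenation_recovers_sequence(self, length):
        cfg = SMALL
        rng = np.random.default_rng(length)
        seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
        assert "".join(chunk_sequence(seq, cfg)) == seq


class TestArchitecture:
    def test_default_feature_vector_is_8192(self):
        assert CNNConfig().feature_dim == 8192
        assert len(CNNConfig().filter_lengths) == 16

    def test_small_grid_arithmetic(self):
        cfg = CNNConfig(filter_lengths=(8, 16, 24, 32), filters_per_length=32)
        assert cfg.feature_dim == 128

    def test_output_width_matches_terms(self):
        terms = [f"GO:{i:07d}" for i in range(1, 12)]
        model = build_model(SMALL, terms)
        assert model.params["dense_w_0"].shape == (11, SMALL.feature_dim)

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            build_model(SMALL, [])

    def test_hyperparameter_grid_enumerates_75_combinations(self):
        grid = hyperparameter_grid()
        assert len(grid) == 75
        assert len({(g.filter_lengths, g.filters_per_length, g.dense_depth)
                    for g in grid}) == 75

    def test_nondecreasing_filter_lengths_enforced(self):
        with pytest.raises(ValueError):
            CNNConfig(filter_lengths=(16, 8))


def tiny_dataset():
    spec = SyntheticSpec(
        n_proteins=60, n_terms_per_namespace=6, seq_length=(80, 120), seed=5
    )
    return simulate_dataset(spec)


def tiny_trained(max_epochs=6):
    ds = tiny_dataset()
    train_truth = ds.truth.restrict_proteins(ds.train_ids)
    terms = select_classes(train_truth, min_count=10)
    cfg = CNNConfig(
        max_len=128, filter_lengths=(8, 12), filters_per_length=16,
        learning_rate=1e-3, batch_size=16, max_epochs=max_epochs, patience=3, seed=2,
    )
    model = train(build_model(cfg, terms), ds.train_records(), train_truth)
    return ds, model


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self):
        ds, model = tiny_trained()
        losses = model.history["train_loss"]
        assert losses[-1] < losses[0]
        _, again = tiny_trained()
        assert again.history == model.history

    def test_missing_sequences_rejected(self):
        ds = tiny_dataset()
        labels = ds.truth
        with pytest.raises(ValueError, match="missing"):
            train(build_model(SMALL, sorted(labels.classes())), [], labels)

    def test_unpropagated_labels_rejected(self):
        ds = tiny_dataset()
        model = build_model(SMALL, sorted(ds.raw.classes()))
        with pytest.raises(ValueError, match="propagated"):
            train(model, ds.records, ds.raw)


class TestPrediction:
    def test_scores_in_unit_interval_and_deterministic(self):
        ds, model = tiny_trained()
        preds1 = model.predict_records(ds.test_records())
        preds2 = model.predict_records(ds.test_records())
        assert preds1 == preds2
        for p in preds1.proteins:
            assert all(0.0 <= s <= 1.0 for s in preds1[p].values())

    def test_padding_and_batch_invariance(self):
        ds, model = tiny_trained()
        rec = ds.test_records()[0]
        long_rec = ds.test_records()[1]
        alone = model.predict_records([rec])
        with_other = model.predict_records([rec, long_rec])
        # batching changes the zero-padding width; scores agree to float32
        # matmul precision (identical batches are bit-identical, see above)
        for term in model.terms:
            assert alone[rec.id][term] == pytest.approx(
                with_other[rec.id][term], abs=1e-5
            )

    def test_chunked_score_is_max_over_chunks(self):
        ds, model = tiny_trained()
        cfg = model.config
        base = ds.test_records()[0].sequence
        long_seq = (base * ((3 * cfg.max_len) // len(base) + 1))[: 3 * cfg.max_len - 50]
        merged = model.predict_records([SequenceRecord("long", long_seq)])
        chunks = chunk_sequence(long_seq, cfg)
        parts = model.predict_records(
            [SequenceRecord(f"c{i}", c) for i, c in enumerate(chunks)]
        )
        for term in model.terms:
            expected = max(parts[f"c{i}"][term] for i in range(len(chunks)))
            assert merged["long"][term] == pytest.approx(expected, abs=1e-6)


class TestFilterActivations:
    def constructed_model(self):
        cfg = CNNConfig(
            max_len=64, filter_lengths=(4,), filters_per_length=2, seed=0
        )
        model = build_model(cfg, ["GO:0000001"])
        w = np.zeros((2, 21, 4), dtype=np.float32)
        for j, aa in enumerate("MKVL"):
            w[0, AA_ALPHABET.index(aa), j] = 1.0
        # filter 1 stays all-zero
        model.params["conv_w_4"] = w
        model.params["conv_b_4"] = np.zeros(2, dtype=np.float32)
        return model

    def test_constructed_filter_finds_its_motif(self):
        model = self.constructed_model()
        seq = "AAAAAMKVLAAAA"
        acts = model.filter_activations(seq)
        best = acts[0]
        assert best.index == 0
        assert best.window == "MKVL"
        assert best.score == pytest.approx(4.0)
        assert best.position == seq.index("MKVL")

    def test_all_zero_filter_scores_zero_at_first_position(self):
        model = self.constructed_model()
        acts = model.filter_activations("AAAAAA")
        zero = [a for a in acts if a.index == 1][0]
        assert zero.score == pytest.approx(0.0)
        assert zero.position == 0

    def test_window_length_always_matches_filter(self):
        ds, model = tiny_trained()
        acts = model.filter_activations(ds.test_records()[0].sequence)
        assert all(len(a.window) == a.length for a in acts)
        scores = [a.score for a in acts]
        assert scores == sorted(scores, reverse=True)

    def test_sequence_shorter_than_smallest_filter_rejected(self):
        model = self.constructed_model()
        with pytest.raises(ValueError, match="short"):
            model.filter_activations("MKV")


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        ds, model = tiny_trained()
        prefix = str(tmp_path / "model")
        model.save(prefix)
        from seqgo.cnn import CNNModel

        loaded = CNNModel.load(prefix)
        assert loaded.terms == model.terms
        assert loaded.config == model.config
        preds = model.predict_records(ds.test_records()[:3])
        assert loaded.predict_records(ds.test_records()[:3]) == preds
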