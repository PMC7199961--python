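import numpy as np
import pytest

import chimeranet as cn
from chimeranet import cnn_model as cm
from chimeranet.chimera_builder import EncodedBatch
from chimeranet.exceptions import ChimeranetError, ValidationError


REFERENCE_PARAM_COUNTS = [144, 0, 1568, 0, 8256, 0, 41088, 0, 0, 0, 114816, 0, 129]
REFERENCE_SHAPES = [
    (110, 16), (55, 16), (55, 32), (28, 32), (28, 64), (14, 64),
    (14, 128), (7, 128), (896,), (896,), (128,), (128,), (1,),
]


class TestArchitectureAccounting:
    def test_default_layer_plan(self):
        arch = cm.build_architecture()
        convs = [l for l in arch.layers if l.kind == "conv"]
        assert [c.filters for c in convs] == [16, 32, 64, 128]
        assert [c.kernel_size for c in convs] == [2, 3, 4, 5]
        pools = [l for l in arch.layers if l.kind == "maxpool"]
        assert [p.pool_size for p in pools] == [2, 2, 2, 2]
        assert arch.layers[-1].units == 1
        assert arch.layers[-1].activation == "sigmoid"

    def test_parameter_counts_per_layer_and_total(self):
        counts, total = cm.count_parameters(cm.build_architecture())
        assert counts == REFERENCE_PARAM_COUNTS
        assert total == 166_001

    def test_output_shape_chain(self):
        assert cm.output_shapes(cm.build_architecture()) == REFERENCE_SHAPES

    def test_single_dense_layer_count(self):
        arch = cm.ArchitectureSpec(
            input_length=10, input_channels=3,
            layers=[cm.LayerSpec("flatten"),
                    cm.LayerSpec("dense", units=1, activation="sigmoid")],
        )
        # d = 10*3 inputs -> u*(d+1)
        assert cm.count_parameters(arch) == ([0, 31], 31)

    def test_minimal_conv_count(self):
        arch = cm.ArchitectureSpec(
            input_length=5, input_channels=1,
            layers=[cm.LayerSpec("conv", filters=1, kernel_size=1, activation="relu"),
                    cm.LayerSpec("flatten"),
                    cm.LayerSpec("dense", units=1, activation="sigmoid")],
        )
        assert cm.count_parameters(arch)[0][0] == 2

    def test_pool_length_uses_ceil(self):
        arch = cm.ArchitectureSpec(
            input_length=9, input_channels=4,
            layers=[cm.LayerSpec("maxpool", pool_size=2),
                    cm.LayerSpec("flatten"),
                    cm.LayerSpec("dense", units=1, activation="sigmoid")],
        )
        assert cm.output_shapes(arch)[0] == (5, 4)

    def test_conv_preserves_length(self):
        arch = cm.ArchitectureSpec(
            input_length=8, input_channels=4,
            layers=[cm.LayerSpec("conv", filters=6, kernel_size=3, activation="relu"),
                    cm.LayerSpec("maxpool", pool_size=2),
                    cm.LayerSpec("flatten"),
                    cm.LayerSpec("dense", units=1, activation="sigmoid")],
        )
        assert cm.output_shapes(arch)[:2] == [(8, 6), (4, 6)]

    def test_non_sigmoid_final_layer_rejected(self):
        with pytest.raises(ValidationError):
            cm.ArchitectureSpec(
                layers=[cm.LayerSpec("dense", units=1, activation="relu")]
            )


def _toy_batch(rng, n):
    idx = rng.integers(0, 4, size=(n, 110))
    data = np.eye(4)[idx]
    labels = rng.integers(0, 2, size=n)
    return EncodedBatch(data, labels)


class TestTraining:
    def test_same_seed_gives_identical_weights(self, rng):
        tr = _toy_batch(rng, 32)
        val = _toy_batch(rng, 16)
        cfg = cm.TrainingConfig(seed=3, max_epochs=2, batch_size=16)
        m1 = cm.train(cm.build_architecture(), tr, val, cfg)
        m2 = cm.train(cm.build_architecture(), tr, val, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_two_example_dataset_is_overfit(self, small_table):
        batch = cn.encode_batch(small_table)
        pos = int(np.flatnonzero(batch.labels == 1)[0])
        neg = int(np.flatnonzero(batch.labels == 0)[0])
        two = EncodedBatch(batch.data[[pos, neg]], batch.labels[[pos, neg]])
        cfg = cm.TrainingConfig(seed=1, max_epochs=30, batch_size=2,
                                early_stop_patience=30)
        model = cm.train(cm.build_architecture(), two, two, cfg)
        losses = [row["train_loss"] for row in model.training_log]
        assert losses[-1] < losses[0]
        assert losses[-1] < 0.2  # essentially memorized

    def test_trained_weight_count_matches_analytic(self, tiny_model):
        assert tiny_model.n_parameters() == cm.count_parameters(tiny_model.architecture)[1]

    def test_training_log_covers_every_epoch(self, tiny_model):
        epochs = [row["epoch"] for row in tiny_model.training_log]
        assert epochs == list(range(len(epochs)))

    def test_empty_training_set_rejected(self, rng):
        val = _toy_batch(rng, 4)
        empty = EncodedBatch(np.zeros((0, 110, 4)), np.zeros(0, dtype=int))
        with pytest.raises(ValidationError):
            cm.train(cm.build_architecture(), empty, val, cm.TrainingConfig())


class TestPredict:
    def test_outputs_are_probabilities_in_input_order(self, tiny_model, rng):
        batch = _toy_batch(rng, 9)
        out = cm.predict(tiny_model, batch)
        assert out.shape == (9,)
        assert ((out >= 0) & (out <= 1)).all()

    def test_duplicated_row_scores_identically(self, tiny_model, rng):
        batch = _toy_batch(rng, 4)
        dup = EncodedBatch(
            np.concatenate([batch.data, batch.data[:1]]),
            np.concatenate([batch.labels, batch.labels[:1]]),
        )
        out = cm.predict(tiny_model, dup)
        # identical up to BLAS remainder-row summation order
        assert out[0] == pytest.approx(out[4], abs=1e-12)

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValidationError):
            cm.predict(tiny_model, np.zeros((2, 100, 4)))


class TestPersistence:
    def test_round_trip_preserves_predictions_bitwise(self, tiny_model, tmp_path, rng):
        batch = _toy_batch(rng, 10)
        cm.save_model(tiny_model, tmp_path / "model")
        loaded = cm.load_model(tmp_path / "model")
        np.testing.assert_array_equal(
            cm.predict(tiny_model, batch), cm.predict(loaded, batch)
        )

    def test_round_trip_preserves_architecture_and_log(self, tiny_model, tmp_path):
        cm.save_model(tiny_model, tmp_path / "model")
        loaded = cm.load_model(tmp_path / "model")
        assert loaded.architecture == tiny_model.architecture
        assert len(loaded.training_log) == len(tiny_model.training_log)
        for a, b in zip(loaded.training_log, tiny_model.training_log):
            assert a["epoch"] == b["epoch"]
            assert a["val_loss"] == pytest.approx(b["val_loss"], rel=1e-9)

    def test_corrupt_artifact_fails_cleanly(self, tiny_model, tmp_path):
        cm.save_model(tiny_model, tmp_path / "model")
        (tmp_path / "model" / "weights.npz").write_bytes(b"not a weights file")
        with pytest.raises(ChimeranetError):
            cm.load_model(tmp_path / "model")

    def test_missing_artifact_fails_cleanly(self, tmp_path):
        with pytest.raises(ChimeranetError):
            cm.load_model(tmp_path / "nonexistent")
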