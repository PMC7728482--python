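"""Architecture contracts, fusion, loss, training behaviour."""

import numpy as np
import pytest

from mlecg import MLCNNBiLSTM, ModelConfig
from mlecg import nn


@pytest.fixture(scope="module")
def full_model():
    """Model at the default (full-size) configuration, untrained."""
    return MLCNNBiLSTM(None, None, None, ModelConfig(seed=1))


@pytest.fixture(scope="module")
def tiny_batch(full_model):
    rng = np.random.default_rng(0)
    x12 = rng.normal(size=(3, 12, 1900))
    return x12, x12[:, 1]


class TestArchitectureShapes:
    def test_channel_outputs_are_256(self, full_model, tiny_batch):
        x12, x2 = tiny_batch
        v1 = full_model.mlcnn_channel_forward(x12)
        v2 = full_model.bilstm_channel_forward(x2)
        assert v1.shape == (3, 256)
        assert v2.shape == (3, 256)

    def test_intermediate_pool_shapes(self, full_model, tiny_batch):
        x12, _ = tiny_batch
        x = x12[:, None]
        shapes = []
        for lay in full_model.mlcnn.layers:
            x = lay.forward(x)
            if isinstance(lay, nn.MaxPool2d):
                shapes.append(x.shape[1:])
        assert shapes == [(32, 6, 950), (64, 3, 475), (128, 1, 237)]

    def test_flatten_size_law(self):
        for T in (1900, 1000, 512):
            cfg = ModelConfig(input_shape=(12, T))
            d = 12
            t = T
            for _ in range(3):
                d, t = d // 2, t // 2
            assert cfg.flatten_dim() == 128 * d * t

    def test_penultimate_features_are_64(self, full_model, tiny_batch):
        x12, x2 = tiny_batch
        probs, feats = full_model._forward(x12, x2)
        assert feats.shape == (3, 64)
        assert probs.shape == (3, 6)

    def test_softmax_rows_sum_to_one(self, full_model, tiny_batch):
        x12, x2 = tiny_batch
        probs, _ = full_model._forward(x12, x2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_binary_variant_two_outputs(self):
        m = MLCNNBiLSTM(None, None, None,
                        ModelConfig.small(n_classes=2, input_shape=(12, 256)))
        rng = np.random.default_rng(1)
        x12 = rng.normal(size=(2, 12, 256))
        probs, _ = m._forward(x12, x12[:, 1])
        assert probs.shape == (2, 2)

    def test_wrong_input_shape_rejected(self, full_model):
        with pytest.raises(ValueError, match="expected"):
            full_model.mlcnn_channel_forward(np.zeros((1, 12, 1000)))
        with pytest.raises(ValueError, match="length"):
            full_model.bilstm_channel_forward(np.zeros((1, 1000)))

    def test_zero_input_zero_bilstm_features(self):
        """Zero sequence with zero biases yields zero hidden states."""
        rng = np.random.default_rng(2)
        lstm = nn.BiLSTM(8, rng)
        lstm.fwd.params["b"][:] = 0.0
        lstm.bwd.params["b"][:] = 0.0
        out = lstm.forward(np.zeros((2, 50)))
        assert np.allclose(out, 0.0)

    def test_fusion_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(mlcnn_fc=256, bilstm_hidden=64).validate()


class TestBiLSTM:
    def test_time_reversal_swaps_directions(self):
        """With tied directional weights, the forward summary of x equals the
        backward summary of reversed x."""
        rng = np.random.default_rng(3)
        lstm = nn.BiLSTM(6, rng)
        for k in lstm.fwd.params:
            lstm.bwd.params[k] = lstm.fwd.params[k].copy()
        x = rng.normal(size=(2, 30))
        out_fwd = lstm.forward(x)
        out_rev = lstm.forward(x[:, ::-1])
        assert np.allclose(out_fwd[:, :6], out_rev[:, 6:], rtol=1e-12)
        assert np.allclose(out_fwd[:, 6:], out_rev[:, :6], rtol=1e-12)

    def test_mean_reduction_shape(self):
        rng = np.random.default_rng(4)
        lstm = nn.BiLSTM(5, rng, reduce="mean")
        assert lstm.forward(rng.normal(size=(3, 20))).shape == (3, 10)


class TestFusion:
    def test_alpha_extremes_and_example(self, full_model):
        v1 = np.array([[1.0, 0.0]])
        v2 = np.array([[0.0, 1.0]])
        from mlecg.model import _Fusion
        assert np.allclose(_Fusion(1.0 - 1e-12).forward(v1, v2), v1)
        assert np.allclose(_Fusion(1e-12).forward(v1, v2), v2, atol=1e-9)
        assert np.allclose(_Fusion(0.7).forward(v1, v2), [[0.7, 0.3]])

    def test_length_mismatch_rejected(self, full_model):
        with pytest.raises(ValueError):
            full_model.fuse(np.zeros((1, 256)), np.zeros((1, 128)))


class TestLoss:
    def test_uniform_probabilities_give_ln_n(self):
        probs = np.full((4, 6), 1 / 6)
        assert nn.cross_entropy(probs, [0, 1, 2, 3]) == pytest.approx(np.log(6))

    def test_one_hot_correct_gives_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert nn.cross_entropy(probs, [0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_arithmetic(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.3, 0.6]])
        want = -(np.log(0.7) + np.log(0.6)) / 2  # independent arithmetic
        assert nn.cross_entropy(probs, [0, 2]) == pytest.approx(want, abs=1e-9)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            nn.cross_entropy(np.full((1, 3), 1 / 3), [3])


class TestTraining:
    def test_separable_two_class_reaches_90_percent(self, trained_small):
        _, res = trained_small
        assert res.train_accuracy >= 0.90
        assert res.final_loss < res.history["loss"].iloc[0]

    def test_masked_weights_zero_after_training(self, trained_small):
        model, _ = trained_small
        off = model.mask.mask == 0
        for lay in model.mlcnn.layers:
            if isinstance(lay, nn.MaskedConv2d):
                assert np.max(np.abs(lay.params["w"][:, :, off])) == 0.0

    def test_alpha_is_learned(self, trained_small):
        model, res = trained_small
        assert res.alpha != model.config.fusion_alpha_init
        assert "alpha" in res.history.columns

    def test_seeded_runs_reproducible(self, two_class_arrays):
        x12, x2, labels = two_class_arrays
        cfg = ModelConfig.small(seed=7)
        h1 = MLCNNBiLSTM(x12, x2, labels, cfg).fit(epochs=3).history
        h2 = MLCNNBiLSTM(x12, x2, labels, cfg).fit(epochs=3).history
        assert np.array_equal(h1["loss"].to_numpy(), h2["loss"].to_numpy())
        assert np.array_equal(h1["alpha"].to_numpy(), h2["alpha"].to_numpy())

    def test_single_class_rejected(self, two_class_arrays):
        x12, x2, _ = two_class_arrays
        m = MLCNNBiLSTM(x12, x2, np.zeros(len(x12), dtype=int),
                        ModelConfig.small(seed=1))
        with pytest.raises(ValueError):
            m.fit(epochs=1)

    def test_empty_dataset_rejected(self):
        m = MLCNNBiLSTM(None, None, None, ModelConfig.small(seed=1))
        with pytest.raises(ValueError):
            m.fit(epochs=1)


class TestFeaturize:
    def test_width_and_determinism(self, trained_small, two_class_arrays):
        _, res = trained_small
        x12, x2, _ = two_class_arrays
        feats = res.featurize(x12[:4], x2[:4])
        assert feats.shape == (4, ModelConfig.small().head[-1])
        dup = res.featurize(np.repeat(x12[:1], 2, 0), np.repeat(x2[:1], 2, 0))
        assert np.array_equal(dup[0], dup[1])

    def test_features_linearly_separable(self, trained_small, two_class_arrays):
        """A linear probe on the penultimate features matches training acc."""
        _, res = trained_small
        x12, x2, labels = two_class_arrays
        feats = res.featurize(x12, x2)
        from sklearn.linear_model import LogisticRegression
        probe = LogisticRegression(max_iter=2000).fit(feats, labels)
        assert probe.score(feats, labels) >= res.train_accuracy


class TestPersistence:
    def test_checkpoint_round_trip(self, trained_small, two_class_arrays, tmp_path):
        model, res = trained_small
        x12, x2, _ = two_class_arrays
        model.save(tmp_path / "ckpt")
        from mlecg.model import MLCNNBiLSTMResults
        loaded = MLCNNBiLSTM.load(tmp_path / "ckpt")
        res2 = MLCNNBiLSTMResults(loaded, res.history)
        p1 = res.predict_proba(x12[:5], x2[:5])
        p2 = res2.predict_proba(x12[:5], x2[:5])
        assert np.allclose(p1, p2, atol=1e-12)

    def test_summary_mentions_alpha_and_mask(self, trained_small):
        _, res = trained_small
        s = res.summary()
        assert "alpha" in s and "full_cross" in s
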