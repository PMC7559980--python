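import numpy as np
import pytest

from violex import (
    ClassifierConfig,
    ConfigError,
    DataError,
    EmbeddingModel,
    Record,
    build_model,
    build_vocab,
    predict_label,
    train_classifier,
)
from violex.classifier import ViolenceClassifier, _stratified_split


@pytest.fixture
def tiny_cfg():
    return ClassifierConfig(
        embedding_dim=8, conv_filters=6, kernel_size=3, pool_size=2,
        lstm_units=5, max_sequence_length=16, batch_size=8, epochs=2, seed=1,
    )


def _tiny_corpus(n=40):
    recs = []
    for i in range(n):
        if i % 4 == 0:
            recs.append(Record(f"v{i}", "patient assaulted by husband reports pain", "V"))
        else:
            recs.append(Record(f"n{i}", "patient fell from the ladder reports pain", "NV"))
    return recs


class TestArchitecture:
    def test_layer_stack_order_and_sizes(self):
        cfg = ClassifierConfig()
        model = build_model({"a": 1, "b": 2}, None, cfg)
        arch = model.architecture()
        assert [l["type"] for l in arch] == [
            "embedding", "dropout", "conv1d", "max_pooling1d", "lstm", "dense",
        ]
        assert arch[0]["output_dim"] == 300 and arch[0]["trainable"]
        assert arch[1]["rate"] == pytest.approx(0.20)
        assert arch[2]["filters"] == 64 and arch[2]["kernel_size"] == 5
        assert arch[2]["activation"] == "relu"
        assert arch[3]["pool_size"] == 4
        assert arch[4]["units"] == 100
        assert arch[5] == {"type": "dense", "units": 1, "activation": "sigmoid"}

    def test_conv_kernel_shape(self):
        cfg = ClassifierConfig()
        model = build_model({"a": 1}, None, cfg)
        # 1-D conv kernel over 300-d embeddings: 5 x 300 x 64
        assert model.params["Wc"].shape == (5 * 300, 64)

    def test_embedding_rows_initialised_from_vectors(self, tiny_cfg):
        vecs = EmbeddingModel(["known"], np.full((1, 8), 0.25))
        model = build_model({"known": 1, "novel": 2}, vecs, tiny_cfg)
        np.testing.assert_allclose(model.params["E"][1], 0.25)
        assert not np.allclose(model.params["E"][2], 0.25)
        assert model.init_oov_rows == 1

    def test_dimension_mismatch_rejected(self, tiny_cfg):
        vecs = EmbeddingModel(["a"], np.zeros((1, 9)))
        with pytest.raises(ConfigError):
            build_model({"a": 1}, vecs, tiny_cfg)

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierConfig(dropout_rate=1.0)


class TestGradients:
    def test_backprop_matches_numerical_gradients(self, tiny_cfg):
        """Analytic gradients of the full stack agree with central differences."""
        vocab = {f"t{i}": i + 1 for i in range(12)}
        model = build_model(vocab, None, tiny_cfg)
        rng = np.random.default_rng(0)
        # keep pre-activations away from the ReLU kink at exactly zero:
        # no all-padding windows, and biases jittered off their zero init
        X = rng.integers(1, 13, size=(3, tiny_cfg.max_sequence_length))
        y = np.array([1.0, 0.0, 1.0])
        for p in model.params.values():
            p += rng.normal(0, 0.01, p.shape)

        _, cache = model._forward(X, train=False, rng=None)
        grads = model._backward(cache, y)

        eps = 1e-6
        check_rng = np.random.default_rng(5)
        for name, P in model.params.items():
            flat_idx = list(np.ndindex(P.shape))
            if len(flat_idx) > 60:
                flat_idx = [flat_idx[i] for i in
                            check_rng.choice(len(flat_idx), 60, replace=False)]
            for ix in flat_idx:
                orig = P[ix]
                P[ix] = orig + eps
                l1 = model.bce(model._forward(X, False, None)[0], y)
                P[ix] = orig - eps
                l2 = model.bce(model._forward(X, False, None)[0], y)
                P[ix] = orig
                numeric = (l1 - l2) / (2 * eps)
                analytic = grads[name][ix]
                assert analytic == pytest.approx(numeric, rel=5e-3, abs=1e-7), name

    def test_zero_dropout_is_identity_at_inference(self, tiny_cfg):
        model = build_model({"a": 1, "b": 2}, None, tiny_cfg)
        X = np.array([[1, 2, 1, 2] + [0] * 12])
        p1, _ = model._forward(X, train=False, rng=None)
        p2, _ = model._forward(X, train=False, rng=None)
        np.testing.assert_array_equal(p1, p2)


class TestTraining:
    def test_single_class_rejected(self, tiny_cfg):
        model = build_model({"a": 1}, None, tiny_cfg)
        recs = [Record(f"r{i}", "a a a", "NV") for i in range(10)]
        with pytest.raises(DataError):
            train_classifier(model, recs, tiny_cfg)

    def test_same_seed_same_weights(self, tiny_cfg):
        recs = _tiny_corpus()
        vocab = build_vocab([r.text.split() for r in recs])
        m1 = build_model(vocab, None, tiny_cfg)
        m2 = build_model(vocab, None, tiny_cfg)
        train_classifier(m1, recs, tiny_cfg)
        train_classifier(m2, recs, tiny_cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_stratified_split_preserves_ratio(self):
        rng = np.random.default_rng(0)
        labels = np.array([1.0] * 34 + [0.0] * 966)
        tr, va = _stratified_split(labels, 0.2, rng)
        assert len(tr) + len(va) == 1000
        # one-record tolerance on the per-split positive counts
        assert abs(labels[va].sum() - 34 * 0.2) <= 1
        assert abs(labels[tr].sum() - 34 * 0.8) <= 1

    def test_training_report_structure(self, tiny_cfg):
        recs = _tiny_corpus()
        vocab = build_vocab([r.text.split() for r in recs])
        model = build_model(vocab, None, tiny_cfg)
        report = train_classifier(model, recs, tiny_cfg)
        assert report["n_train"] + report["n_val"] == len(recs)
        assert len(report["history"]) >= 1
        for h in report["history"]:
            assert set(h) >= {"epoch", "train_loss", "val_loss", "val_f1_v"}
        assert model.trained


class TestPrediction:
    def _trained(self, tiny_cfg):
        recs = _tiny_corpus()
        vocab = build_vocab([r.text.split() for r in recs])
        model = build_model(vocab, None, tiny_cfg)
        train_classifier(model, recs, tiny_cfg)
        return model

    def test_empty_text_yields_valid_prediction(self, tiny_cfg):
        model = self._trained(tiny_cfg)
        pred = predict_label(model, Record("e", ""))
        assert 0.0 <= pred.probability <= 1.0
        assert pred.label in ("V", "NV")

    def test_inference_deterministic(self, tiny_cfg):
        model = self._trained(tiny_cfg)
        rec = Record("x", "patient assaulted by husband reports pain")
        p1 = predict_label(model, rec)
        p2 = predict_label(model, rec)
        assert p1.probability == p2.probability

    def test_save_load_round_trip(self, tiny_cfg, tmp_path):
        model = self._trained(tiny_cfg)
        rec = Record("x", "patient assaulted by husband")
        before = predict_label(model, rec).probability
        model.save(tmp_path / "clf")
        loaded = ViolenceClassifier.load(tmp_path / "clf")
        assert predict_label(loaded, rec).probability == pytest.approx(before)
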