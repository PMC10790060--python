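"""Volumetric CNN: architecture contract, gradients, training behavior."""

import numpy as np
import pytest

from csecnn.cnn import (
    ArchitectureError,
    CNNVolumeClassifier,
    ModelSpec,
    TrainHyper,
    _Network,
    build_model,
    desk_scale_spec,
)

MICRO = ModelSpec(
    input_extents=(12, 12, 12),
    avgpool_size=2,
    conv_filters=(2, 4, 4),
    conv_kernels=(3, 2, 2),
    maxpool_sizes=(1, 1),
    fc_widths=(8, 8, 8, 2),
)


def blob_data(rng, n, extents=(12, 12, 12), shift=2.0):
    X = rng.standard_normal((n, *extents))
    y = np.arange(n) % 2
    X[y == 1, 3:8, 3:8, 3:8] += shift
    return X, y


class TestArchitecture:
    def test_full_size_layer_contract(self):
        spec = build_model((91, 109, 91))
        summary = spec.layer_summary()
        convs = [s for s in summary if s["layer"].startswith("conv")]
        assert [c["filters"] for c in convs] == [32, 64, 128]
        assert [c["kernel"] for c in convs] == [(3, 3, 3), (3, 3, 3), (2, 2, 2)]
        pools = [s for s in summary if s["layer"].startswith(("avgpool", "maxpool"))]
        assert all(p["size"] == 2 for p in pools) and len(pools) == 3
        assert [s["layer"] for s in summary if s["layer"].startswith("batchnorm")] == [
            "batchnorm1", "batchnorm2",
        ]
        fcs = [s for s in summary if s["layer"].startswith("fc")]
        assert [f["output"][0] for f in fcs] == [500, 500, 500, 2]
        assert summary[-1]["layer"] == "softmax"

    def test_too_small_extents_name_failing_layer(self):
        with pytest.raises(ArchitectureError, match="conv1"):
            build_model((2, 2, 2))

    def test_desk_profile_keeps_layer_sequence(self):
        spec = desk_scale_spec((24, 24, 24))
        names = [s["layer"] for s in spec.layer_summary()]
        assert names[0] == "avgpool"
        assert [n for n in names if n.startswith("conv")] == ["conv1", "conv2", "conv3"]
        assert names[-1] == "softmax"

    def test_final_width_must_be_two(self):
        with pytest.raises(ValueError):
            ModelSpec((24, 24, 24), fc_widths=(16, 3))

    def test_hyper_validation(self):
        with pytest.raises(ValueError):
            TrainHyper(early_stop_patience=500, max_epochs=400)
        with pytest.raises(ValueError):
            TrainHyper(learning_rate=0)


def test_gradients_match_finite_differences():
    spec = ModelSpec(
        input_extents=(8, 8, 8), avgpool_size=2, conv_filters=(2, 2, 2),
        conv_kernels=(2, 2, 2), maxpool_sizes=(1, 1), fc_widths=(4, 4, 4, 2),
    )
    rng = np.random.default_rng(3)
    net = _Network(spec, rng)
    # move biases and batchnorm offsets off zero so no ReLU sits exactly at
    # its kink, where one-sided derivatives would spoil the comparison
    for _, layer in net.layers:
        for key, p in layer.params.items():
            if p.ndim == 1:
                p += rng.normal(0.1, 0.05, size=p.shape)
    X = rng.standard_normal((5, 8, 8, 8))
    Y = np.zeros((5, 2))
    Y[np.arange(5), rng.integers(0, 2, 5)] = 1

    def loss():
        probs = net.forward(X, train=True)
        return float(-np.sum(Y * np.log(probs + 1e-12)) / 5)

    net.loss_and_grad(X, Y)
    checked = 0
    for name, layer in net.layers:
        for key, p in layer.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            analytic = layer.grads[key][idx]
            eps = 1e-5
            p[idx] += eps
            lp = loss()
            p[idx] -= 2 * eps
            lm = loss()
            p[idx] += eps
            numeric = (lp - lm) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=1e-3, abs=1e-6), (
                f"{name}.{key}"
            )
            checked += 1
    assert checked >= 10


class TestTraining:
    def test_overfits_separable_blobs(self):
        rng = np.random.default_rng(0)
        X, y = blob_data(rng, 40)
        clf = CNNVolumeClassifier(spec=MICRO, random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0
        assert clf.n_epochs_ <= 400

    def test_shuffled_labels_stay_at_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for rep in range(20):
            X = rng.standard_normal((24, 12, 12, 12))
            y = rng.permutation(np.arange(24) % 2)
            Xv = rng.standard_normal((12, 12, 12, 12))
            yv = rng.permutation(np.arange(12) % 2)
            clf = CNNVolumeClassifier(
                spec=MICRO, max_epochs=30, early_stop_patience=30, random_state=rep
            )
            clf.fit(X, y, validation_data=(Xv, yv))
            accs.append((clf.predict(Xv) == yv).mean())
        # 240 pooled chance predictions: binomial 95% band around 0.5 is
        # roughly +-0.07; allow slack for within-run correlation
        assert 0.38 <= np.mean(accs) <= 0.62

    def test_early_stopping_stops_patience_after_best(self):
        rng = np.random.default_rng(2)
        X, y = blob_data(rng, 16)
        Xv = rng.standard_normal((8, 12, 12, 12))  # unlearnable validation
        yv = np.arange(8) % 2
        clf = CNNVolumeClassifier(
            spec=MICRO, max_epochs=200, early_stop_patience=5, random_state=0
        )
        clf.fit(X, y, validation_data=(Xv, yv))
        assert clf.n_epochs_ < 200
        assert clf.n_epochs_ == clf.best_epoch_ + 5

    def test_seeded_training_reproducible(self):
        rng = np.random.default_rng(4)
        X, y = blob_data(rng, 16)
        runs = []
        for _ in range(2):
            clf = CNNVolumeClassifier(spec=MICRO, max_epochs=20,
                                      early_stop_patience=20, random_state=5)
            clf.fit(X, y)
            runs.append(clf.history_["monitor_loss"])
        assert runs[0] == runs[1]

    def test_single_class_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 12, 12, 12))
        with pytest.raises(ValueError, match="both classes"):
            CNNVolumeClassifier(spec=MICRO).fit(X, np.zeros(6))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(6)
    X, y = blob_data(rng, 20)
    clf = CNNVolumeClassifier(spec=MICRO, max_epochs=60,
                              early_stop_patience=60, random_state=1)
    return clf.fit(X, y), X, y


class TestPredict:
    def test_probabilities_sum_to_one(self, fitted):
        clf, X, _ = fitted
        probs = clf.predict_proba(X)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_volume_identical_probabilities(self, fitted):
        clf, X, _ = fitted
        probs = clf.predict_proba(np.stack([X[0], X[0]]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_extent_mismatch_rejected(self, fitted):
        clf, _, _ = fitted
        with pytest.raises(ValueError, match="extents"):
            clf.predict(np.zeros((1, 10, 10, 10)))

    def test_checkpoint_roundtrip(self, fitted, tmp_path):
        clf, X, _ = fitted
        clf.save(tmp_path / "model")
        back = CNNVolumeClassifier.load(tmp_path / "model")
        np.testing.assert_array_equal(back.predict_proba(X), clf.predict_proba(X))
        assert back.best_epoch_ == clf.best_epoch_
        assert (tmp_path / "model.history.tsv").exists()
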