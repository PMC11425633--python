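import numpy as np
import pytest

from deglutio import _nn
from deglutio import classifier as clf
from deglutio import dataset as ds
from deglutio import simulate as sim
from deglutio.labels import CLASS_LABELS


TINY_ARCH = clf.ArchitectureConfig(
    conv_first=((6, 5), (6, 3), (6, 3)), conv_second=(6, 3),
    lstm_units=4, dense_units=(12, 16, 8), input_len=100,
)

# same layers at the real 500-sample input, for training on Epoch objects
TOY_ARCH = clf.ArchitectureConfig(
    conv_first=((6, 5), (6, 3), (6, 3)), conv_second=(6, 3),
    lstm_units=4, dense_units=(12, 16, 8),
)


def expected_param_count(arch: clf.ArchitectureConfig) -> int:
    """Analytic layer-by-layer parameter sum, independent of the build path."""
    total = 0
    c_in = arch.input_channels
    f2, k2 = arch.conv_second
    for f1, k1 in arch.conv_first:
        total += k1 * c_in * f1 + f1          # conv A
        total += 2 * f1 + f1                  # bn gamma/beta + prelu
        total += k2 * f1 * f2 + f2            # conv B
        total += 2 * f2 + f2
        c_in = f2
    h = arch.lstm_units
    total += 2 * (4 * h * (c_in + h + 1))     # both LSTM directions
    d_in = 2 * h
    for units in arch.dense_units:
        total += d_in * units + units + units  # dense + prelu
        d_in = units
    total += d_in * arch.n_classes + arch.n_classes
    return total


def toy_split(n_per_class=24, seed=0):
    """Linearly separable 2-label toy: energy early vs late in the window."""
    rng = np.random.default_rng(seed)
    epochs = []
    pids = ["P1", "P2", "P3", "P4", "P5"]
    for i in range(n_per_class):
        for label in ("rest", "cough"):
            x = rng.uniform(0, 0.2, size=(3, ds.EPOCH_SAMPLES))
            if label == "rest":
                x[:, :250] += 0.7
            else:
                x[:, 250:] += 0.7
            epochs.append(ds.Epoch(np.clip(x, 0, 1), label, pids[i % 5]))
    return ds.interpatient_split(epochs, seed=seed)


class TestArchitectureConfig:
    def test_published_defaults(self):
        a = clf.PUBLISHED_ARCH
        assert a.conv_first == ((80, 5), (48, 3), (112, 3))
        assert a.conv_second == (16, 4)
        assert a.lstm_units == 10
        assert a.dense_units == (140, 512, 256)
        assert a.dropout_after_second_dense == 0.2
        assert a.learning_rate == 0.001
        assert a.n_classes == 7
        assert (a.input_len, a.input_channels) == (500, 3)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            clf.ArchitectureConfig(lstm_units=0)
        with pytest.raises(ValueError):
            clf.ArchitectureConfig(dropout_after_second_dense=1.0)
        with pytest.raises(ValueError):
            clf.ArchitectureConfig(learning_rate=0.0)


class TestBuild:
    def test_parameter_count_matches_analytic_sum(self):
        _, n = clf.build(clf.PUBLISHED_ARCH, seed=0)
        assert n == expected_param_count(clf.PUBLISHED_ARCH)

    def test_parameter_count_tiny_arch(self):
        _, n = clf.build(TINY_ARCH, seed=0)
        assert n == expected_param_count(TINY_ARCH)

    def test_build_deterministic_shapes(self):
        m1, _ = clf.build(clf.PUBLISHED_ARCH, seed=5)
        m2, _ = clf.build(clf.PUBLISHED_ARCH, seed=5)
        assert all(a.shape == b.shape for a, b in zip(m1.params, m2.params))
        assert all(np.array_equal(a, b) for a, b in zip(m1.params, m2.params))

    def test_output_dimension_seven(self):
        m, _ = clf.build(clf.PUBLISHED_ARCH, seed=0)
        x = np.random.default_rng(0).uniform(size=(2, 500, 3)).astype(np.float32)
        assert m.forward(x).shape == (2, 7)

    def test_pooling_floor_rule(self):
        # 500 -> 250 -> 125 -> 62 through the three pool-by-2 stages
        m, _ = clf.build(clf.PUBLISHED_ARCH, seed=0)
        x = np.random.default_rng(0).uniform(size=(1, 500, 3)).astype(np.float32)
        out = x
        for layer in m.layers:
            out = layer.forward(out)
            if isinstance(layer, _nn.BiLSTM):
                break
        assert out.shape == (1, 20)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        _nn_dtype = _nn.DTYPE
        _nn.DTYPE = np.float64
        try:
            arch = clf.ArchitectureConfig(
                conv_first=((4, 3), (3, 3), (4, 3)), conv_second=(3, 2),
                lstm_units=3, dense_units=(5, 6, 4), n_classes=3,
                input_len=24, input_channels=2, dropout_after_second_dense=0.0)
            m, _ = clf.build(arch, seed=1)
            rng = np.random.default_rng(0)
            x = rng.uniform(size=(4, 24, 2))
            y = np.eye(3)[rng.integers(0, 3, 4)]

            def loss_fn():
                return _nn.softmax_cross_entropy(m.forward(x, training=True), y)[0]

            _, _, g = _nn.softmax_cross_entropy(m.forward(x, training=True), y)
            m.backward(g)
            analytic = [gr.copy() for gr in m.grads]
            errs = []
            eps = 1e-6
            for pi, p in enumerate(m.params):
                flat = p.reshape(-1)
                for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    orig = flat[k]
                    flat[k] = orig + eps
                    lp = loss_fn()
                    flat[k] = orig - eps
                    lm = loss_fn()
                    flat[k] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = analytic[pi].reshape(-1)[k]
                    errs.append(abs(num - ana) / max(abs(num), abs(ana), 1e-8))
            errs = np.sort(errs)
            # kink crossings (PReLU at 0, pool ties) may spoil isolated entries
            assert np.median(errs) < 1e-6
            assert errs[int(0.95 * len(errs))] < 1e-4
        finally:
            _nn.DTYPE = _nn_dtype


class TestTrain:
    def test_toy_separable_reaches_perfect_validation(self):
        split = toy_split()
        run = clf.train(split, TOY_ARCH, max_epochs=50, seed=0, batch_size=16,
                        patience=None)
        assert run.best_val_accuracy == 1.0
        assert run.epochs_trained <= 50

    def test_seeded_determinism_epoch1_loss(self):
        split = toy_split()
        r1 = clf.train(split, TOY_ARCH, max_epochs=1, seed=3)
        r2 = clf.train(split, TOY_ARCH, max_epochs=1, seed=3)
        assert abs(r1.history["loss"][0] - r2.history["loss"][0]) < 1e-6

    def test_best_checkpoint_is_max_val_accuracy(self):
        split = toy_split()
        run = clf.train(split, TOY_ARCH, max_epochs=10, seed=1)
        assert run.best_val_accuracy == max(run.history["val_accuracy"])

    def test_beats_chance_on_toy(self):
        split = toy_split()
        run = clf.train(split, TOY_ARCH, max_epochs=30, seed=2)
        assert run.history["accuracy"][-1] >= 5 * (1 / 7)

    def test_empty_validation_rejected(self):
        split = toy_split()
        bad = ds.DatasetSplit(train=split.train, validation=[], test=split.test)
        with pytest.raises(ValueError, match="empty"):
            clf.train(bad, TOY_ARCH, max_epochs=1)


@pytest.fixture(scope="module")
def tiny_model():
    m, _ = clf.build(TINY_ARCH, seed=0)
    return m


class TestPredict:

    def test_rows_sum_to_one(self, tiny_model):
        x = np.random.default_rng(0).uniform(size=(5, 100, 3))
        p = clf.predict(tiny_model, x)
        assert p.shape == (5, 7)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_epoch_identical_rows(self, tiny_model):
        x = np.random.default_rng(1).uniform(size=(1, 100, 3))
        p = clf.predict(tiny_model, np.vstack([x, x]))
        assert np.array_equal(p[0], p[1])

    def test_batch_invariance(self, tiny_model):
        x = np.random.default_rng(2).uniform(size=(7, 100, 3))
        full = clf.predict(tiny_model, x)
        singles = np.vstack([clf.predict(tiny_model, x[i : i + 1]) for i in range(7)])
        assert np.allclose(full, singles, atol=1e-5)

    def test_wrong_shape_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="emg1, emg2, sound"):
            clf.predict(tiny_model, np.zeros((2, 100, 5)))

    def test_unnormalized_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="normalized"):
            clf.predict(tiny_model, np.full((1, 100, 3), 7.0))


class _StubModel:
    """Emits fixed logits per window; counts evaluated rows."""

    def __init__(self, label_for_window):
        self.label_for_window = label_for_window
        self.windows_seen = 0
        self._cursor = 0

    def forward(self, x, training=False):
        out = np.full((len(x), 7), -10.0)
        for i in range(len(x)):
            out[i, self.label_for_window(self._cursor + i)] = 10.0
        self._cursor += len(x)
        self.windows_seen += len(x)
        return out


def rest_recording_250(duration_s=10.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * 250)
    return sim.MultimodalRecording(
        rng.normal(size=n), rng.normal(size=n), rng.normal(size=n), 250.0, "P1", [])


class TestClassifySession:
    def test_rest_only_single_event(self):
        stub = _StubModel(lambda k: 0)
        events = clf.classify_session(stub, rest_recording_250())
        assert len(events) == 1
        assert events[0].label == "rest"
        assert events[0].start_s == 0.0
        assert events[0].end_s == pytest.approx(10.0)

    def test_window_arithmetic_41_windows(self):
        stub = _StubModel(lambda k: 0)
        clf.classify_session(stub, rest_recording_250(10.0))
        assert stub.windows_seen == 41  # (10 - 2) / 0.2 + 1

    def test_event_boundaries_partition_duration(self):
        stub = _StubModel(lambda k: 5 if 10 <= k < 25 else 0)
        events = clf.classify_session(stub, rest_recording_250(12.0))
        total = sum(e.duration_s for e in events)
        assert total == pytest.approx(12.0)
        assert [e.label for e in events] == ["rest", "cough", "rest"]

    def test_short_blips_absorbed(self):
        stub = _StubModel(lambda k: 5 if k == 12 else 0)  # one isolated window
        events = clf.classify_session(stub, rest_recording_250(10.0), min_event_s=0.4)
        assert [e.label for e in events] == ["rest"]

    def test_short_recording_rejected(self):
        stub = _StubModel(lambda k: 0)
        with pytest.raises(ValueError, match="2-s"):
            clf.classify_session(stub, rest_recording_250(1.5))

    def test_wrong_rate_rejected(self):
        rng = np.random.default_rng(0)
        rec = sim.MultimodalRecording(rng.normal(size=4000), rng.normal(size=4000),
                                      rng.normal(size=4000), 2000.0, "P1", [])
        with pytest.raises(ValueError, match="250"):
            clf.classify_session(_StubModel(lambda k: 0), rec)


class TestSerialization:
    def test_round_trip_identical_predictions(self, tmp_path):
        m, _ = clf.build(TINY_ARCH, seed=4)
        path = tmp_path / "model.npz"
        clf.save_model(m, TINY_ARCH, path)
        m2, arch2 = clf.load_model(path)
        assert arch2 == TINY_ARCH
        x = np.random.default_rng(5).uniform(size=(3, 100, 3))
        assert np.array_equal(clf.predict(m, x), clf.predict(m2, x))
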