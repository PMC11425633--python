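"""CNN-BiLSTM swallowing-status classifier.

Three convolutional blocks (two Conv1D layers each, batch-normalized, PReLU,
max-pooled), a 10-unit bidirectional LSTM, three PReLU dense layers with a
0.2 dropout after the second, and a 7-way softmax head.  Trained with Adam
(lr 0.001) on categorical cross-entropy; the checkpoint with the best
validation accuracy is kept.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from deglutio import _nn
from deglutio.dataset import (
    EPOCH_S, EPOCH_SAMPLES, MODEL_FS_HZ, DatasetSplit, Epoch, epochs_to_arrays,
)
from deglutio.labels import CLASS_LABELS, N_CLASSES
from deglutio.simulate import MultimodalRecording

__all__ = [
    "ArchitectureConfig",
    "TrainingRun",
    "TimelineEvent",
    "build",
    "train",
    "predict",
    "classify_session",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """The published architecture hyperparameters as a validated value object."""

    conv_first: tuple[tuple[int, int], ...] = ((80, 5), (48, 3), (112, 3))
    conv_second: tuple[int, int] = (16, 4)
    pool_size: int = 2
    lstm_units: int = 10
    dense_units: tuple[int, ...] = (140, 512, 256)
    dropout_after_second_dense: float = 0.2
    n_classes: int = 7
    input_len: int = EPOCH_SAMPLES
    input_channels: int = 3
    learning_rate: float = 0.001

    def __post_init__(self) -> None:
        counts = [f for f, _ in self.conv_first] + [k for _, k in self.conv_first]
        counts += [*self.conv_second, self.pool_size, self.lstm_units, *self.dense_units,
                   self.n_classes, self.input_len, self.input_channels]
        if min(counts) <= 0:
            raise ValueError("all layer sizes must be positive")
        if not 0 <= self.dropout_after_second_dense < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


PUBLISHED_ARCH = ArchitectureConfig()


def build(arch: ArchitectureConfig, seed: int = 0) -> tuple[_nn.Sequential, int]:
    """Instantiate the network; returns (model, trainable parameter count).

    Temporal length through the blocks follows the floor rule of
    non-overlapping pooling: L -> floor(L / pool) per block.
    """
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    c_in = arch.input_channels
    for filters, kernel in arch.conv_first:
        layers.append(_nn.Conv1D(c_in, filters, kernel, rng))
        layers.append(_nn.BatchNorm(filters))
        layers.append(_nn.PReLU(filters))
        f2, k2 = arch.conv_second
        layers.append(_nn.Conv1D(filters, f2, k2, rng))
        layers.append(_nn.BatchNorm(f2))
        layers.append(_nn.PReLU(f2))
        layers.append(_nn.MaxPool1D(arch.pool_size))
        c_in = f2
    layers.append(_nn.BiLSTM(c_in, arch.lstm_units, rng))
    d_in = 2 * arch.lstm_units
    dropout_rng = np.random.default_rng(rng.integers(0, 2**63))
    for i, units in enumerate(arch.dense_units):
        layers.append(_nn.Dense(d_in, units, rng))
        layers.append(_nn.PReLU(units))
        if i == 1 and arch.dropout_after_second_dense > 0:
            layers.append(_nn.Dropout(arch.dropout_after_second_dense, dropout_rng))
        d_in = units
    layers.append(_nn.Dense(d_in, arch.n_classes, rng))
    model = _nn.Sequential(layers)
    return model, model.n_params


@dataclass
class TrainingRun:
    history: dict[str, list[float]]
    best_weights: list[np.ndarray]
    seed: int
    epochs_trained: int
    model: _nn.Sequential
    arch: ArchitectureConfig

    @property
    def best_val_accuracy(self) -> float:
        return max(self.history["val_accuracy"])

    def restore_best(self) -> _nn.Sequential:
        self.model.set_state(self.best_weights)
        return self.model


def _check_xy(x: np.ndarray, y: np.ndarray, arch: ArchitectureConfig, name: str) -> None:
    if len(x) == 0:
        raise ValueError(f"{name} set is empty")
    if x.shape[1:] != (arch.input_len, arch.input_channels):
        raise ValueError(f"{name} inputs must be (n, {arch.input_len}, {arch.input_channels})")
    if y.shape != (len(x), arch.n_classes) or not np.allclose(y.sum(axis=1), 1.0):
        raise ValueError(f"{name} one-hot targets malformed")


def train(
    split: DatasetSplit,
    arch: ArchitectureConfig = PUBLISHED_ARCH,
    max_epochs: int = 300,
    seed: int = 0,
    batch_size: int = 32,
    patience: int | None = None,
    verbose: bool = False,
) -> TrainingRun:
    """Train on the split's training set, checkpointing on validation accuracy.

    Deterministic given (split, arch, max_epochs, seed, batch_size).
    ``patience`` stops early after that many epochs without a validation-
    accuracy improvement; ``None`` runs all ``max_epochs``.
    """
    x_tr, _, y_tr = epochs_to_arrays(split.train)
    x_va, _, y_va = epochs_to_arrays(split.validation)
    _check_xy(x_tr, y_tr, arch, "train")
    _check_xy(x_va, y_va, arch, "validation")

    rng = np.random.default_rng(seed)
    model, _ = build(arch, seed=int(rng.integers(0, 2**63)))
    opt = _nn.Adam(model.params, lr=arch.learning_rate)

    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [],
    }
    best_state = model.get_state()
    best_acc = -1.0
    stale = 0
    n = len(x_tr)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i0 in range(0, n, batch_size):
            idx = order[i0 : i0 + batch_size]
            logits = model.forward(x_tr[idx], training=True)
            loss, probs, grad = _nn.softmax_cross_entropy(logits, y_tr[idx])
            model.backward(grad)
            opt.step(model.grads)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(1) == y_tr[idx].argmax(1)).sum())
        history["loss"].append(sum(losses) / n)
        history["accuracy"].append(correct / n)

        va_logits = model.forward(x_va, training=False)
        va_loss, va_probs, _ = _nn.softmax_cross_entropy(va_logits, y_va)
        va_acc = float((va_probs.argmax(1) == y_va.argmax(1)).mean())
        history["val_loss"].append(va_loss)
        history["val_accuracy"].append(va_acc)
        if verbose:
            print(f"epoch {epoch + 1}: loss={history['loss'][-1]:.4f} "
                  f"acc={history['accuracy'][-1]:.3f} val_acc={va_acc:.3f}")

        if va_acc > best_acc:
            best_acc = va_acc
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if patience is not None and stale >= patience:
                break

    model.set_state(best_state)
    return TrainingRun(
        history=history, best_weights=best_state, seed=seed,
        epochs_trained=len(history["loss"]), model=model, arch=arch,
    )


def _to_input_array(epochs) -> np.ndarray:
    if isinstance(epochs, np.ndarray):
        x = epochs
        if x.ndim == 2:
            if x.shape[0] == 3:
                x = x.T[None, :, :]
            else:
                x = x[None, :, :]
        return np.asarray(x, dtype=np.float64)
    if isinstance(epochs, Epoch):
        epochs = [epochs]
    x, _, _ = epochs_to_arrays(list(epochs))
    return x


def predict(model: _nn.Sequential, epochs, batch_size: int = 256) -> np.ndarray:
    """Class probabilities, one row per epoch, in the canonical label order."""
    x = _to_input_array(epochs)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("inputs must be (n, time, 3) with channels (emg1, emg2, sound)")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("inputs must be normalized to [0, 1]")
    rows = []
    for i0 in range(0, len(x), batch_size):
        logits = model.forward(x[i0 : i0 + batch_size], training=False)
        rows.append(_nn.softmax(logits))
    return np.vstack(rows)


@dataclass
class TimelineEvent:
    start_s: float
    end_s: float
    label: str
    mean_prob: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def classify_session(
    model: _nn.Sequential,
    recording: MultimodalRecording,
    hop_s: float = 0.2,
    min_event_s: float = 0.4,
) -> list[TimelineEvent]:
    """Sliding-window classification of a preprocessed (250 Hz) recording.

    2-s windows at ``hop_s`` hop; per-window argmax; runs of identical labels
    merge into events (boundaries midway between adjacent window centers, so
    event durations partition the recording exactly); events shorter than
    ``min_event_s`` are absorbed into their longer neighbor.
    """
    from deglutio.dataset import normalize_epoch

    if abs(recording.fs_hz - MODEL_FS_HZ) > 1e-6:
        raise ValueError("recording must be preprocessed to the 250 Hz model rate")
    dur = recording.duration_s
    if dur < EPOCH_S:
        raise ValueError("recording shorter than one 2-s window")
    n_win = int(np.floor((dur - EPOCH_S) / hop_s + 1e-9)) + 1
    starts = np.arange(n_win) * hop_s
    chans = recording.channels()
    fs = recording.fs_hz
    wins = []
    for s in starts:
        i0 = int(round(s * fs))
        wins.append(normalize_epoch(chans[:, i0 : i0 + EPOCH_SAMPLES]).T)
    probs = predict(model, np.stack(wins))
    labels = probs.argmax(axis=1)

    centers = starts + EPOCH_S / 2
    # runs of identical labels -> event list with midpoint boundaries
    runs: list[list[int]] = [[0]]
    for k in range(1, n_win):
        if labels[k] == labels[runs[-1][-1]]:
            runs[-1].append(k)
        else:
            runs.append([k])

    def _bounds(runs_list):
        bounds = [0.0]
        for a, b in zip(runs_list[:-1], runs_list[1:]):
            bounds.append(float((centers[a[-1]] + centers[b[0]]) / 2))
        bounds.append(dur)
        return bounds

    ev_labels = [int(labels[r[0]]) for r in runs]
    bounds = _bounds(runs)

    # absorb short events into the longer adjacent neighbor
    def _durations():
        return [bounds[i + 1] - bounds[i] for i in range(len(ev_labels))]

    while len(ev_labels) > 1:
        durs = _durations()
        short = [i for i, d in enumerate(durs) if d < min_event_s]
        if not short:
            break
        i = min(short, key=lambda j: durs[j])
        left = durs[i - 1] if i > 0 else -1.0
        right = durs[i + 1] if i < len(ev_labels) - 1 else -1.0
        if left >= right:
            del ev_labels[i]
            del bounds[i]
        else:
            del ev_labels[i]
            del bounds[i + 1]
        # merge now-adjacent identical labels
        j = 1
        while j < len(ev_labels):
            if ev_labels[j] == ev_labels[j - 1]:
                del ev_labels[j]
                del bounds[j]
            else:
                j += 1

    events = []
    for i, lab in enumerate(ev_labels):
        s, e = bounds[i], bounds[i + 1]
        inside = (centers >= s - 1e-9) & (centers <= e + 1e-9)
        p = float(probs[inside, lab].mean()) if inside.any() else float("nan")
        events.append(TimelineEvent(s, e, CLASS_LABELS[lab], p))
    return events


def save_model(run_or_model, arch: ArchitectureConfig, path) -> None:
    """Serialize weights + architecture to an .npz container with a version tag."""
    model = run_or_model.model if isinstance(run_or_model, TrainingRun) else run_or_model
    state = model.get_state()
    meta = json.dumps({"version": 1, "arch": asdict(arch)})
    np.savez(path, meta=np.array(meta), n=np.array(len(state)),
             **{f"arr_{i}": a for i, a in enumerate(state)})


def load_model(path) -> tuple[_nn.Sequential, ArchitectureConfig]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("version") != 1:
            raise ValueError("unsupported model container version")
        arch_d = meta["arch"]
        for key in ("conv_first", "dense_units"):
            arch_d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in arch_d[key])
        arch_d["conv_second"] = tuple(arch_d["conv_second"])
        arch = ArchitectureConfig(**arch_d)
        state = [data[f"arr_{i}"] for i in range(int(data["n"]))]
    model, _ = build(arch, seed=0)
    model.set_state(state)
    return model, arch
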