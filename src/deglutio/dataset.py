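"""Epoching, normalization, shift augmentation and participant-disjoint splits.

Epochs are 2-s, 3-channel windows at the 250 Hz model rate (3 x 500), scaled
per channel to [0, 1].  Splits assign whole participants to train/validation/
test so augmented copies of one subject can never leak across partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from deglutio.labels import LABEL_INDEX, N_CLASSES, validate_label
from deglutio.simulate import MultimodalRecording

__all__ = [
    "Epoch",
    "DatasetSplit",
    "EPOCH_S",
    "MODEL_FS_HZ",
    "EPOCH_SAMPLES",
    "SHIFT_S",
    "normalize_epoch",
    "one_hot",
    "segment",
    "augment",
    "interpatient_split",
    "epochs_to_arrays",
]

EPOCH_S = 2.0
MODEL_FS_HZ = 250.0
EPOCH_SAMPLES = int(EPOCH_S * MODEL_FS_HZ)  # 500
SHIFT_S = 0.2


def normalize_epoch(raw: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Scale each channel of a (3, n) window to [0, 1].

    A constant channel maps to all 0.5 (degenerate rule).  ``method="zscore"``
    standardizes instead and then squashes through a logistic to stay in
    [0, 1]; min-max is the default contract.
    """
    x = np.asarray(raw, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a (channels, samples) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite entries in epoch")
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    if method == "minmax":
        out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.5)
    elif method == "zscore":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out = 1.0 / (1.0 + np.exp(-z))
    else:
        raise ValueError("method must be 'minmax' or 'zscore'")
    return out


@dataclass
class Epoch:
    """One normalized 2-s analysis window."""

    values: np.ndarray  # (3, 500), entries in [0, 1]
    label: str
    participant_id: str
    shift_s: float = 0.0
    start_s: float = 0.0  # window onset in the source recording

    def __post_init__(self) -> None:
        validate_label(self.label)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (3, EPOCH_SAMPLES):
            raise ValueError(f"epoch values must be (3, {EPOCH_SAMPLES}), got {self.values.shape}")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("epoch values must lie in [0, 1]; normalize first")
        if self.shift_s < 0:
            raise ValueError("shift_s must be >= 0")

    @property
    def label_index(self) -> int:
        return LABEL_INDEX[self.label]


def one_hot(label: str) -> np.ndarray:
    validate_label(label)
    v = np.zeros(N_CLASSES)
    v[LABEL_INDEX[label]] = 1.0
    return v


def _extract_window(rec: MultimodalRecording, start_s: float) -> np.ndarray | None:
    fs = rec.fs_hz
    i0 = int(round(start_s * fs))
    i1 = i0 + EPOCH_SAMPLES
    if i0 < 0 or i1 > rec.n_samples:
        return None
    return rec.channels()[:, i0:i1]


def segment(rec: MultimodalRecording, include_rest: bool = True) -> list[Epoch]:
    """Cut a preprocessed (250 Hz) recording into labeled epochs.

    One epoch per annotated event, anchored at the event start; events longer
    than 2 s tile into consecutive non-overlapping epochs; trailing partials
    are discarded.  Gaps between events yield rest epochs the same way.
    """
    if abs(rec.fs_hz - MODEL_FS_HZ) > 1e-6:
        raise ValueError(f"recording must be resampled to {MODEL_FS_HZ} Hz before epoching")
    if rec.duration_s < EPOCH_S:
        raise ValueError(f"recording shorter than one {EPOCH_S}-s epoch")

    epochs: list[Epoch] = []
    anns = sorted(rec.annotations, key=lambda a: a.start_s)
    for ann in anns:
        n_tiles = max(1, int(ann.duration_s // EPOCH_S))
        for k in range(n_tiles):
            win = _extract_window(rec, ann.start_s + k * EPOCH_S)
            if win is None:
                break
            epochs.append(
                Epoch(normalize_epoch(win), ann.class_label, rec.participant_id,
                      shift_s=0.0, start_s=ann.start_s + k * EPOCH_S)
            )
    if include_rest:
        edges = [0.0]
        for ann in anns:
            edges.extend([ann.start_s, ann.end_s])
        edges.append(rec.duration_s)
        for g0, g1 in zip(edges[::2], edges[1::2]):
            k = 0
            while g0 + (k + 1) * EPOCH_S <= g1 + 1e-9:
                win = _extract_window(rec, g0 + k * EPOCH_S)
                if win is None:
                    break
                epochs.append(
                    Epoch(normalize_epoch(win), "rest", rec.participant_id,
                          shift_s=0.0, start_s=g0 + k * EPOCH_S)
                )
                k += 1
    epochs.sort(key=lambda e: e.start_s)
    return epochs


def _window_label(rec: MultimodalRecording, start_s: float) -> str:
    """Majority-overlap label of the window [start_s, start_s + 2 s).

    The event class wins when its annotation covers at least half the window
    (exact half breaks toward the non-rest class); otherwise the window is
    rest.  Between two events the larger overlap wins, earlier event on ties.
    """
    end_s = start_s + EPOCH_S
    best_lab, best_ov = "rest", 0.0
    for ann in sorted(rec.annotations, key=lambda a: a.start_s):
        ov = min(end_s, ann.end_s) - max(start_s, ann.start_s)
        if ov > best_ov + 1e-12:
            best_lab, best_ov = ann.class_label, ov
    if best_ov >= EPOCH_S / 2 - 1e-9:
        return best_lab
    return "rest"


def augment(
    epochs: list[Epoch],
    rec: MultimodalRecording,
    shift_s: float = SHIFT_S,
    n_shifts: int = 0,
) -> tuple[list[Epoch], int]:
    """Add time-shifted copies of each epoch, re-labeled by majority overlap.

    Returns ``(all_epochs, n_skipped)`` where shifted windows falling past the
    recording end are skipped and tallied.  ``n_shifts=0`` is the identity.
    """
    if shift_s <= 0:
        raise ValueError("shift_s must be positive")
    if n_shifts < 0:
        raise ValueError("n_shifts must be >= 0")
    out = list(epochs)
    skipped = 0
    for ep in epochs:
        for k in range(1, n_shifts + 1):
            start = ep.start_s + k * shift_s
            win = _extract_window(rec, start)
            if win is None:
                skipped += 1
                continue
            out.append(
                Epoch(normalize_epoch(win), _window_label(rec, start),
                      ep.participant_id, shift_s=k * shift_s, start_s=start)
            )
    return out, skipped


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    train: list[Epoch]
    validation: list[Epoch]
    test: list[Epoch]
    ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self) -> None:
        parts = [self.participants("train"), self.participants("validation"),
                 self.participants("test")]
        for a, b in itertools.combinations(parts, 2):
            if a & b:
                raise ValueError(f"participant leakage between split partitions: {a & b}")

    def participants(self, which: str) -> set[str]:
        return {e.participant_id for e in getattr(self, which)}

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)

    def one_hot_matrix(self, which: str) -> np.ndarray:
        eps = getattr(self, which)
        m = np.zeros((len(eps), N_CLASSES))
        for i, e in enumerate(eps):
            m[i, e.label_index] = 1.0
        return m


def _assignment_cost(counts: np.ndarray, assign: np.ndarray, targets: np.ndarray) -> float:
    achieved = np.array([counts[assign == s].sum() for s in range(3)])
    return float(np.abs(achieved - targets).sum())


def _exhaustive_assign(counts: np.ndarray, targets: np.ndarray) -> np.ndarray:
    n = len(counts)
    best, best_cost = None, np.inf
    for combo in itertools.product(range(3), repeat=n):
        assign = np.array(combo)
        if len(set(combo)) < 3:
            continue
        cost = _assignment_cost(counts, assign, targets)
        if cost < best_cost - 1e-12:
            best, best_cost = assign, cost
    assert best is not None
    return best


def _greedy_assign(counts: np.ndarray, targets: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    n = len(counts)
    order = rng.permutation(n)
    order = order[np.argsort(-counts[order], kind="stable")]
    assign = np.full(n, -1)
    filled = np.zeros(3)
    for i in order:
        deficits = targets - filled
        s = int(np.argmax(deficits))
        assign[i] = s
        filled[s] += counts[i]
    # local refinement: single moves then pairwise swaps until no improvement
    improved = True
    while improved:
        improved = False
        cost = _assignment_cost(counts, assign, targets)
        for i in range(n):
            for s in range(3):
                if s == assign[i]:
                    continue
                old = assign[i]
                if np.sum(assign == old) == 1:
                    continue  # would empty a partition
                assign[i] = s
                c = _assignment_cost(counts, assign, targets)
                if c < cost - 1e-12:
                    cost, improved = c, True
                else:
                    assign[i] = old
        for i in range(n):
            for j in range(i + 1, n):
                if assign[i] == assign[j]:
                    continue
                assign[i], assign[j] = assign[j], assign[i]
                c = _assignment_cost(counts, assign, targets)
                if c < cost - 1e-12:
                    cost, improved = c, True
                else:
                    assign[i], assign[j] = assign[j], assign[i]
    return assign


def interpatient_split(
    epochs: list[Epoch],
    ratio: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Assign whole participants to train/validation/test near the target ratio.

    Small cohorts (<= 12 participants) are solved exactly by enumeration;
    larger ones by a seeded greedy fill plus move/swap refinement.  Raises
    with fewer than 3 participants (three disjoint non-empty sets impossible).
    """
    if abs(sum(ratio) - 1.0) > 1e-9 or min(ratio) <= 0:
        raise ValueError("ratio must be three positive fractions summing to 1")
    pids = sorted({e.participant_id for e in epochs})
    if len(pids) < 3:
        raise ValueError("interpatient split requires at least 3 distinct participants")
    counts = np.array([sum(1 for e in epochs if e.participant_id == p) for p in pids])
    targets = np.array(ratio) * counts.sum()

    if len(pids) <= 12:
        assign = _exhaustive_assign(counts, targets)
    else:
        assign = _greedy_assign(counts, targets, np.random.default_rng(seed))

    sets: list[list[Epoch]] = [[], [], []]
    pid_to_set = {p: int(s) for p, s in zip(pids, assign)}
    for e in epochs:
        sets[pid_to_set[e.participant_id]].append(e)
    return DatasetSplit(train=sets[0], validation=sets[1], test=sets[2], ratio=ratio)


def epochs_to_arrays(epochs: list[Epoch]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack epochs into (n, 500, 3) inputs, integer labels and one-hot targets."""
    if not epochs:
        return (np.zeros((0, EPOCH_SAMPLES, 3)), np.zeros(0, dtype=int),
                np.zeros((0, N_CLASSES)))
    x = np.stack([e.values.T for e in epochs])  # (n, time, channels)
    y = np.array([e.label_index for e in epochs])
    oh = np.zeros((len(epochs), N_CLASSES))
    oh[np.arange(len(epochs)), y] = 1.0
    return x, y, oh
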