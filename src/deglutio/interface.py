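"""Configuration, recording I/O and the end-to-end pipeline.

Recordings travel as delimited text: ``<stem>.tsv`` holds time + the three
channels with ``# key=value`` header lines, and ``<stem>.annotations.tsv`` is
the mandatory event sidecar.  The sound channel can be mirrored to 16-bit PCM
WAV.  ``run_pipeline`` chains simulate -> preprocess -> dataset -> train ->
evaluate -> report on synthetic data, all randomness flowing from one seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from deglutio import classifier as clf
from deglutio import dataset as ds
from deglutio import evaluation as ev
from deglutio import signalproc as sp
from deglutio import simulate as sim
from deglutio.labels import CLASS_LABELS, EVENT_LABELS

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "sound_to_wav",
    "sound_from_wav",
    "run_pipeline",
]

log = logging.getLogger("deglutio")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _from_dict(cls, data: dict):
    import typing

    hints = typing.get_type_hints(cls)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        ftype = hints.get(f.name)
        if dataclasses.is_dataclass(ftype) and isinstance(v, dict):
            v = _from_dict(ftype, v)
        elif isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    n_participants: int = 20
    events_per_participant: int = 8
    gap_s: float = 5.0
    emg_white_uV: float = 1.5
    sound_white: float = 0.012
    powerline_uV: float = 1.0
    gain_low: float = 0.75
    gain_high: float = 1.3

    def noise_spec(self) -> sim.NoiseSpec:
        return sim.NoiseSpec(self.emg_white_uV, self.sound_white, self.powerline_uV)


@dataclass
class FilterConfig:
    emg_band_hz: tuple = (20.0, 100.0)
    notch_band_hz: tuple = (59.0, 61.0)
    sound_band_hz: tuple = (10.0, 900.0)
    model_fs_hz: float = 250.0
    acquisition_fs_hz: float = 2000.0
    noise_reduction: bool = False

    def spec(self) -> sp.FilterSpec:
        return sp.FilterSpec(
            tuple(self.emg_band_hz), tuple(self.notch_band_hz),
            tuple(self.sound_band_hz), self.model_fs_hz, self.acquisition_fs_hz,
        )


@dataclass
class DatasetConfig:
    shift_s: float = 0.2
    n_shifts: int = 2
    ratio: tuple = (0.6, 0.2, 0.2)


@dataclass
class TrainConfig:
    max_epochs: int = 120
    batch_size: int = 32
    patience: int | None = 25
    learning_rate: float = 0.001


@dataclass
class ReportConfig:
    hop_s: float = 0.2
    min_event_s: float = 0.4
    placement_threshold_db: float = 6.0


@dataclass
class PipelineConfig:
    """All tunables of the chain, grouped per stage."""

    version: str = "1"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------


def write_recording(recording: sim.MultimodalRecording, path) -> Path:
    """Write a recording as TSV + annotation sidecar; returns the data path."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(recording.n_samples) / recording.fs_hz
    header = (
        f"# fs_hz={recording.fs_hz}\n"
        f"# participant_id={recording.participant_id}\n"
        "time_s\temg1_uV\temg2_uV\tsound"
    )
    data = np.column_stack([t, recording.emg_ch1, recording.emg_ch2, recording.sound])
    np.savetxt(path, data, fmt="%.6f", delimiter="\t", header=header, comments="")
    side = path.with_suffix(".annotations.tsv")
    with open(side, "w") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for a in sorted(recording.annotations, key=lambda x: x.start_s):
            fh.write(f"{a.start_s:.6f}\t{a.end_s:.6f}\t{a.class_label}\n")
    return path


def read_recording(path) -> sim.MultimodalRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    side = path.with_suffix(".annotations.tsv")
    if not side.exists():
        raise FileNotFoundError(f"missing annotation sidecar: expected {side}")
    fs_hz = None
    participant = "unknown"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "fs_hz":
                fs_hz = float(val)
            elif key.strip() == "participant_id":
                participant = val.strip()
    if fs_hz is None:
        raise ValueError(f"{path}: missing '# fs_hz=' header line")
    data = np.loadtxt(path, delimiter="\t", skiprows=3)
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (time, emg1, emg2, sound), "
                         f"got shape {data.shape}")
    annotations = []
    with open(side) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{side}:{lineno}: expected 3 tab-separated fields")
            annotations.append(sim.EventAnnotation(float(parts[0]), float(parts[1]), parts[2]))
    return sim.MultimodalRecording(
        data[:, 1], data[:, 2], data[:, 3], fs_hz, participant, annotations
    )


def sound_to_wav(recording: sim.MultimodalRecording, path) -> Path:
    """Mirror the sound channel to 16-bit PCM WAV; scale stored in a JSON sidecar."""
    from scipy.io import wavfile

    path = Path(path).with_suffix(".wav")
    path.parent.mkdir(parents=True, exist_ok=True)
    scale = float(np.max(np.abs(recording.sound)))
    if scale == 0:
        scale = 1.0
    ints = np.round(recording.sound / scale * 32767.0).astype(np.int16)
    wavfile.write(path, int(recording.fs_hz), ints)
    path.with_suffix(".wav.json").write_text(json.dumps({"scale": scale}))
    return path


def sound_from_wav(path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    path = Path(path)
    meta = json.loads(path.with_suffix(".wav.json").read_text())
    fs, ints = wavfile.read(path)
    return ints.astype(np.float64) / 32767.0 * meta["scale"], float(fs)


# ---------------------------------------------------------------------------
# the chained pipeline
# ---------------------------------------------------------------------------


def build_epochs(
    recordings: list[sim.MultimodalRecording],
    cfg: PipelineConfig,
) -> list[ds.Epoch]:
    """Preprocess, segment and augment every recording."""
    spec = cfg.filters.spec()
    epochs: list[ds.Epoch] = []
    for rec in recordings:
        pre = sp.preprocess_recording(rec, spec, noise_reduction=cfg.filters.noise_reduction)
        eps = ds.segment(pre)
        eps, _ = ds.augment(eps, pre, shift_s=cfg.dataset.shift_s,
                            n_shifts=cfg.dataset.n_shifts)
        epochs.extend(eps)
    return epochs


def run_pipeline(config: PipelineConfig, seed: int | None = None, out_dir="pipeline_out") -> dict:
    """Execute the full chain on synthetic data; returns artifact paths.

    Stages: simulate -> preprocess/epoch -> split -> train -> evaluate ->
    classify one held-out session -> report.  Each stage logs its parameters;
    rerunning with the same seed reproduces the split membership and the
    initial model state.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    artifacts = {"config": out / "config.yaml"}
    stage = "simulate"
    try:
        log.info("stage=simulate participants=%d events=%d seed=%d",
                 config.simulate.n_participants, config.simulate.events_per_participant,
                 config.seed)
        mix = {lab: 1.0 / len(EVENT_LABELS) for lab in EVENT_LABELS}
        recordings = sim.generate_session(
            config.simulate.n_participants, config.simulate.events_per_participant,
            mix, noise=config.simulate.noise_spec(), seed=config.seed,
            gap_s=config.simulate.gap_s,
            gain_range=(config.simulate.gain_low, config.simulate.gain_high),
        )
        rec_dir = out / "recordings"
        for rec in recordings:
            write_recording(rec, rec_dir / rec.participant_id)
        artifacts["recordings"] = rec_dir

        stage = "dataset"
        epochs = build_epochs(recordings, config)
        split = ds.interpatient_split(epochs, tuple(config.dataset.ratio), seed=config.seed)
        log.info("stage=dataset epochs=%d split=%s", len(epochs), split.counts)
        split_info = {
            "counts": split.counts,
            "participants": {w: sorted(split.participants(w))
                             for w in ("train", "validation", "test")},
        }
        (out / "dataset.json").write_text(json.dumps(split_info, indent=2))
        artifacts["dataset"] = out / "dataset.json"

        stage = "train"
        arch = dataclasses.replace(clf.PUBLISHED_ARCH,
                                   learning_rate=config.train.learning_rate)
        run = clf.train(split, arch, max_epochs=config.train.max_epochs,
                        seed=config.seed, batch_size=config.train.batch_size,
                        patience=config.train.patience)
        log.info("stage=train epochs_trained=%d best_val_acc=%.3f",
                 run.epochs_trained, run.best_val_accuracy)
        clf.save_model(run, arch, out / "model.npz")
        artifacts["model"] = out / "model.npz"

        stage = "evaluate"
        x_te, y_te, _ = ds.epochs_to_arrays(split.test)
        probs = clf.predict(run.model, x_te)
        cm = ev.confusion([CLASS_LABELS[i] for i in y_te],
                          [CLASS_LABELS[i] for i in probs.argmax(1)])
        metrics = {
            "test_accuracy": cm.accuracy(),
            "confusion_matrix": cm.counts.tolist(),
            "per_class": cm.per_class_metrics(),
            "split_counts": split.counts,
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        artifacts["metrics"] = out / "metrics.json"

        stage = "report"
        test_pid = sorted(split.participants("test"))[0]
        rec = next(r for r in recordings if r.participant_id == test_pid)
        pre = sp.preprocess_recording(rec, config.filters.spec())
        timeline = clf.classify_session(run.model, pre, hop_s=config.report.hop_s,
                                        min_event_s=config.report.min_event_s)
        ev.session_report(timeline, cm=cm, recording=pre, out_dir=out / "report")
        artifacts["report"] = out / "report"
    except Exception as exc:  # noqa: BLE001 - annotate failing stage, keep partial artifacts
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return artifacts
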