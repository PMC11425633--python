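"""Confusion-matrix metrics, electrode-placement QC and session reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from deglutio.labels import CLASS_LABELS, LABEL_INDEX, N_CLASSES, validate_label
from deglutio.signalproc import snr_db
from deglutio.simulate import MultimodalRecording

__all__ = [
    "ConfusionMatrix",
    "PlacementCheck",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "placement_check",
    "session_report",
    "PLACEMENT_THRESHOLD_DB",
]

PLACEMENT_THRESHOLD_DB = 6.0


@dataclass
class ConfusionMatrix:
    """7x7 count table; rows are true classes, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"counts must be {N_CLASSES}x{N_CLASSES}")
        if np.any(c < 0) or not np.all(c == np.floor(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return accuracy(self)

    def sensitivity(self, class_label: str) -> float:
        return sensitivity(self, class_label)

    def specificity(self, class_label: str) -> float:
        return specificity(self, class_label)

    def per_class_metrics(self) -> dict[str, dict[str, float | None]]:
        """Per-class one-vs-rest metrics; None where a denominator is empty."""
        out: dict[str, dict[str, float | None]] = {}
        for lab in CLASS_LABELS:
            row: dict[str, float | None] = {}
            for name, fn in (("sensitivity", sensitivity), ("specificity", specificity)):
                try:
                    row[name] = fn(self, lab)
                except ValueError:
                    row[name] = None
            out[lab] = row
        return out


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    t = [validate_label(l) for l in true_labels]
    p = [validate_label(l) for l in predicted_labels]
    if len(t) != len(p):
        raise ValueError("label sequences must have equal length")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for a, b in zip(t, p):
        counts[LABEL_INDEX[a], LABEL_INDEX[b]] += 1
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("accuracy undefined on an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def sensitivity(cm: ConfusionMatrix, class_label: str) -> float:
    """TP / (TP + FN) for the class, one-vs-rest."""
    i = LABEL_INDEX[validate_label(class_label)]
    row = cm.counts[i].sum()
    if row == 0:
        raise ValueError(f"sensitivity undefined: no true {class_label} samples")
    return float(cm.counts[i, i] / row)


def specificity(cm: ConfusionMatrix, class_label: str) -> float:
    """TN / (TN + FP) for the class, one-vs-rest."""
    i = LABEL_INDEX[validate_label(class_label)]
    neg = cm.total - cm.counts[i].sum()
    if neg == 0:
        raise ValueError(f"specificity undefined: no true non-{class_label} samples")
    fp = cm.counts[:, i].sum() - cm.counts[i, i]
    return float((neg - fp) / neg)


@dataclass
class PlacementCheck:
    """Per-location SNR verdicts for the EMG pre-test."""

    snr_db: dict[str, float]
    threshold_db: float = PLACEMENT_THRESHOLD_DB
    verdict: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.verdict = {loc: v > self.threshold_db for loc, v in self.snr_db.items()}


def placement_check(
    pre_test_recording: MultimodalRecording,
    threshold_db: float = PLACEMENT_THRESHOLD_DB,
    noise_window_s: float = 2.0,
    amplitude: str = "rms",
) -> PlacementCheck:
    """SNR-based electrode-placement QC on a water-swallow pre-test recording.

    The first annotated swallow is the signal window; the ``noise_window_s``
    of inactivity immediately preceding it is the noise window.  A location
    passes when its SNR exceeds ``threshold_db`` (default 6 dB).
    """
    anns = sorted(pre_test_recording.annotations, key=lambda a: a.start_s)
    if not anns:
        raise ValueError(
            "placement check needs at least one annotated swallow; "
            "record two water swallows with a 5-s interval first"
        )
    first = anns[0]
    fs = pre_test_recording.fs_hz
    n0 = int(first.start_s * fs)
    n_noise = int(noise_window_s * fs)
    if n0 < max(n_noise // 4, 16):
        raise ValueError(
            "no usable inactivity segment before the first swallow; "
            "start the recording with a few seconds of rest"
        )
    i_noise0 = max(0, n0 - n_noise)
    n1 = int(first.end_s * fs)
    snrs = {}
    for loc, series in (("emg_ch1", pre_test_recording.emg_ch1),
                        ("emg_ch2", pre_test_recording.emg_ch2)):
        res = snr_db(series[n0:n1], series[i_noise0:n0], amplitude=amplitude)
        snrs[loc] = res.snr_db
    return PlacementCheck(snr_db=snrs, threshold_db=threshold_db)


def session_report(
    timeline,
    cm: ConfusionMatrix | None = None,
    recording: MultimodalRecording | None = None,
    out_dir=None,
    plots: bool = False,
) -> dict:
    """Summarize a classified session.

    Returns a machine-readable dict (per-class event counts and durations,
    flagged aspiration events with timestamps, optional metrics); when
    ``out_dir`` is given, writes ``summary.json`` + ``report.txt`` and, with
    ``plots=True`` and a recording, spectrogram/EMG-envelope figures.
    """
    events = [
        {"start_s": round(ev.start_s, 3), "end_s": round(ev.end_s, 3),
         "label": ev.label, "mean_prob": round(ev.mean_prob, 4)}
        for ev in timeline
    ]
    per_class = {
        lab: {
            "count": sum(1 for e in events if e["label"] == lab),
            "total_duration_s": round(sum(e["end_s"] - e["start_s"]
                                          for e in events if e["label"] == lab), 3),
        }
        for lab in CLASS_LABELS
    }
    aspirations = [e for e in events if e["label"] == "silent_aspiration"]
    summary = {
        "n_events": len(events),
        "events": events,
        "per_class": per_class,
        "silent_aspiration_flags": [
            {"start_s": e["start_s"], "end_s": e["end_s"]} for e in aspirations
        ],
        "message": None if events else "no events detected",
    }
    if cm is not None:
        summary["metrics"] = {
            "accuracy": cm.accuracy(),
            "confusion_matrix": cm.counts.tolist(),
            "per_class": cm.per_class_metrics(),
        }

    lines = ["Swallowing session report", "=" * 25]
    if not events:
        lines.append("no events detected")
    for lab in CLASS_LABELS:
        pc = per_class[lab]
        lines.append(f"{lab:>18}: {pc['count']:3d} events, {pc['total_duration_s']:8.2f} s")
    if aspirations:
        lines.append("")
        lines.append("!! SILENT ASPIRATION FLAGS")
        for e in aspirations:
            lines.append(f"   at {e['start_s']:.2f}-{e['end_s']:.2f} s")
    if cm is not None:
        lines.append("")
        lines.append(f"test accuracy: {100 * cm.accuracy():.2f}%")
    text = "\n".join(lines) + "\n"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "report.txt").write_text(text)
        if plots and recording is not None:
            _write_plots(recording, out)
    return summary


def _write_plots(recording: MultimodalRecording, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.signal import hilbert

    from deglutio.signalproc import spectrogram

    t = np.arange(recording.n_samples) / recording.fs_hz
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    for ax, (name, series) in zip(
        axes[:2], (("EMG ch1 (digastric)", recording.emg_ch1),
                   ("EMG ch2 (sternohyoid)", recording.emg_ch2))
    ):
        env = np.abs(hilbert(series))
        ax.plot(t, series, lw=0.4, alpha=0.6)
        ax.plot(t, env, lw=1.0)
        ax.set_ylabel(name)
    f, tt, sxx = spectrogram(recording.sound, recording.fs_hz)
    axes[2].pcolormesh(tt, f, 20 * np.log10(sxx + 1e-12), shading="auto")
    axes[2].set_ylabel("sound (Hz)")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(out / "signals.png", dpi=100)
    plt.close(fig)
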