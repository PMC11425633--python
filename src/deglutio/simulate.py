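"""Synthetic multimodal swallowing-session generator.

Produces dual-channel EMG (microvolts) plus a neck-microphone channel
(arbitrary units) at 2 kHz with ground-truth event annotations.  The temporal
grammar of a normal swallow is: a suprahyoid (digastric) burst leading the
first sound wave, an infrahyoid (sternohyoid) burst between the first and
second sound waves, and three sound packets in strict order.  Silent
aspiration stretches the whole event, desynchronizes sounds from muscle
activity and weakens the infrahyoid burst.  Cough is a single broadband sound
blast with brief EMG co-activation; chewing is a rhythmic train of suprahyoid
bursts with faint sound.

All quantitative defaults (amplitudes, carrier frequencies, durations,
jitter scales) are simulator parameters, not measured device values; they are
chosen so the seven classes are separable but overlapping enough that
classification is non-trivial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from deglutio.labels import SWALLOW_LABELS, validate_label

__all__ = [
    "SwallowTemplate",
    "EventTruth",
    "EventAnnotation",
    "MultimodalRecording",
    "NoiseSpec",
    "default_template",
    "render_event",
    "generate_session",
    "is_sequence_coherent",
]

DEFAULT_FS_HZ = 2000.0
#: rest gap between consecutive events (protocol-style pacing)
DEFAULT_GAP_S = 5.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwallowTemplate:
    """Timing/intensity blueprint for a single event of one class.

    Onsets are relative to the event start (seconds).  ``transit_scale``
    stretches every onset and duration at render time; ``desync_jitter_s``
    is the scale of the sound-vs-muscle timing perturbation (0 for normal
    classes).
    """

    class_label: str
    emg1_onset_s: float
    emg1_duration_s: float
    emg1_amplitude_uV: float
    emg2_onset_s: float
    emg2_duration_s: float
    emg2_amplitude_uV: float
    ssw_onsets_s: tuple[float, float, float]
    ssw_durations_s: tuple[float, float, float]
    desync_jitter_s: float = 0.0
    transit_scale: float = 1.0

    def __post_init__(self) -> None:
        validate_label(self.class_label)
        if len(self.ssw_onsets_s) != 3 or len(self.ssw_durations_s) != 3:
            raise ValueError("ssw_onsets_s and ssw_durations_s must have length 3")
        if min(self.emg1_duration_s, self.emg2_duration_s, *self.ssw_durations_s) <= 0:
            raise ValueError("all durations must be strictly positive")
        if min(self.emg1_amplitude_uV, self.emg2_amplitude_uV) < 0:
            raise ValueError("amplitudes must be non-negative")
        if min(self.emg1_onset_s, self.emg2_onset_s, *self.ssw_onsets_s) < 0:
            raise ValueError("onsets must be non-negative")
        if self.transit_scale <= 0:
            raise ValueError("transit_scale must be positive")
        if self.desync_jitter_s < 0:
            raise ValueError("desync_jitter_s must be non-negative")
        if self.class_label in SWALLOW_LABELS:
            o1, o2, o3 = self.ssw_onsets_s
            if not (o1 < o2 < o3):
                raise ValueError("normal swallow requires strictly increasing SSW onsets")
            if self.emg1_onset_s > o1:
                raise ValueError("digastric burst must not start after the first sound wave")
            if not (o1 <= self.emg2_onset_s <= o2):
                raise ValueError(
                    "sternohyoid burst onset must fall between the first and second sound waves"
                )
        if self.class_label == "silent_aspiration":
            if self.transit_scale <= 1.0:
                raise ValueError("silent aspiration requires transit_scale > 1")
            if self.desync_jitter_s <= 0:
                raise ValueError("silent aspiration requires desync_jitter_s > 0")

    @property
    def nominal_duration_s(self) -> float:
        """Span of the slowest-finishing component after transit stretching."""
        ends = [
            self.emg1_onset_s + self.emg1_duration_s,
            self.emg2_onset_s + self.emg2_duration_s,
            *(o + d for o, d in zip(self.ssw_onsets_s, self.ssw_durations_s)),
        ]
        return self.transit_scale * max(ends)


@dataclass(frozen=True)
class EventTruth:
    """Realized (post-jitter) event timing, relative to the event start."""

    class_label: str
    emg1_onset_s: float
    emg1_end_s: float
    emg2_onset_s: float
    emg2_end_s: float
    ssw_onsets_s: tuple[float, float, float]
    ssw_ends_s: tuple[float, float, float]


@dataclass
class EventAnnotation:
    """A labeled interval of a recording, with optional generative ground truth."""

    start_s: float
    end_s: float
    class_label: str
    truth: SwallowTemplate | None = None
    realized: EventTruth | None = None

    def __post_init__(self) -> None:
        validate_label(self.class_label)
        if not self.start_s < self.end_s:
            raise ValueError("annotation requires start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class MultimodalRecording:
    """Synchronized EMG x2 + sound at a single sampling rate."""

    emg_ch1: np.ndarray
    emg_ch2: np.ndarray
    sound: np.ndarray
    fs_hz: float
    participant_id: str
    annotations: list[EventAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emg_ch1 = np.asarray(self.emg_ch1, dtype=np.float64)
        self.emg_ch2 = np.asarray(self.emg_ch2, dtype=np.float64)
        self.sound = np.asarray(self.sound, dtype=np.float64)
        if not (len(self.emg_ch1) == len(self.emg_ch2) == len(self.sound)):
            raise ValueError("all three channels must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        dur = self.duration_s
        prev_end = -np.inf
        for ann in sorted(self.annotations, key=lambda a: a.start_s):
            if ann.start_s < 0 or ann.end_s > dur + 1e-9:
                raise ValueError(
                    f"annotation [{ann.start_s}, {ann.end_s}] outside recording of {dur:.3f}s"
                )
            if ann.start_s < prev_end - 1e-9:
                raise ValueError("annotated events overlap")
            prev_end = ann.end_s

    @property
    def n_samples(self) -> int:
        return len(self.sound)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channels(self) -> np.ndarray:
        """Stack channels as a (3, n) array in (emg1, emg2, sound) order."""
        return np.stack([self.emg_ch1, self.emg_ch2, self.sound])


@dataclass(frozen=True)
class NoiseSpec:
    """Additive baseline noise configuration."""

    emg_white_uV: float = 1.5
    sound_white: float = 0.012
    powerline_uV: float = 1.0
    powerline_hz: float = 60.0

    def validate(self) -> "NoiseSpec":
        if min(self.emg_white_uV, self.sound_white, self.powerline_uV) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        return self


DEFAULT_NOISE = NoiseSpec()

# probability that an aspiration render actually receives the gross
# sound-vs-EMG delay (the remaining fraction only gets onset jitter)
ASPIRATION_DESYNC_PROB = 0.9
# magnitude range of the gross delay, seconds
ASPIRATION_DELAY_RANGE_S = (0.35, 0.7)

_SSW_CARRIERS_HZ = (92.0, 74.0, 84.0)  # per-wave carriers, inside the 250 Hz model band


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

_TEMPLATES: dict[str, SwallowTemplate] = {
    "rest": SwallowTemplate(
        class_label="rest",
        emg1_onset_s=0.0, emg1_duration_s=0.5, emg1_amplitude_uV=0.0,
        emg2_onset_s=0.0, emg2_duration_s=0.5, emg2_amplitude_uV=0.0,
        ssw_onsets_s=(0.1, 0.2, 0.3), ssw_durations_s=(0.1, 0.1, 0.1),
    ),
    "liquid": SwallowTemplate(
        class_label="liquid",
        emg1_onset_s=0.10, emg1_duration_s=0.50, emg1_amplitude_uV=40.0,
        emg2_onset_s=0.38, emg2_duration_s=0.50, emg2_amplitude_uV=34.0,
        ssw_onsets_s=(0.22, 0.55, 0.90), ssw_durations_s=(0.14, 0.12, 0.14),
    ),
    "soft_food": SwallowTemplate(
        class_label="soft_food",
        emg1_onset_s=0.10, emg1_duration_s=0.65, emg1_amplitude_uV=54.0,
        emg2_onset_s=0.46, emg2_duration_s=0.62, emg2_amplitude_uV=46.0,
        ssw_onsets_s=(0.26, 0.66, 1.08), ssw_durations_s=(0.16, 0.14, 0.16),
    ),
    "dense_food": SwallowTemplate(
        class_label="dense_food",
        emg1_onset_s=0.10, emg1_duration_s=0.82, emg1_amplitude_uV=70.0,
        emg2_onset_s=0.55, emg2_duration_s=0.78, emg2_amplitude_uV=60.0,
        ssw_onsets_s=(0.30, 0.80, 1.30), ssw_durations_s=(0.18, 0.16, 0.18),
    ),
    "silent_aspiration": SwallowTemplate(
        class_label="silent_aspiration",
        emg1_onset_s=0.10, emg1_duration_s=0.55, emg1_amplitude_uV=38.0,
        emg2_onset_s=0.40, emg2_duration_s=0.50, emg2_amplitude_uV=15.0,
        ssw_onsets_s=(0.22, 0.55, 0.90), ssw_durations_s=(0.14, 0.12, 0.14),
        desync_jitter_s=0.08, transit_scale=1.6,
    ),
    "cough": SwallowTemplate(
        class_label="cough",
        emg1_onset_s=0.10, emg1_duration_s=0.22, emg1_amplitude_uV=46.0,
        emg2_onset_s=0.12, emg2_duration_s=0.22, emg2_amplitude_uV=40.0,
        ssw_onsets_s=(0.12, 0.3, 0.5), ssw_durations_s=(0.30, 0.05, 0.05),
    ),
    "chewing": SwallowTemplate(
        class_label="chewing",
        emg1_onset_s=0.10, emg1_duration_s=0.30, emg1_amplitude_uV=42.0,
        emg2_onset_s=0.15, emg2_duration_s=0.30, emg2_amplitude_uV=8.0,
        ssw_onsets_s=(0.15, 0.8, 1.45), ssw_durations_s=(0.06, 0.06, 0.06),
    ),
}

#: chewing renders this many suprahyoid bursts at CHEW_INTERVAL_S spacing
CHEW_COUNT = 4
CHEW_INTERVAL_S = 0.65

_SOUND_AMPLITUDE = {  # arbitrary units, per class archetype
    "rest": 0.0,
    "liquid": 0.50,
    "soft_food": 0.55,
    "dense_food": 0.60,
    "silent_aspiration": 0.42,
    "cough": 1.30,
    "chewing": 0.07,
}


def default_template(class_label: str) -> SwallowTemplate:
    """Return the built-in template for ``class_label``.

    Consistency classes scale monotonically (liquid < soft_food < dense_food
    in burst duration and amplitude); the aspiration template stretches
    transit and weakens the sternohyoid burst.
    """
    validate_label(class_label)
    return _TEMPLATES[class_label]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS white noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    hi = min(hi, 0.999 * fs / 2)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _place(series: np.ndarray, fs: float, onset_s: float, burst: np.ndarray) -> None:
    """Add ``burst`` into ``series`` starting at ``onset_s``, clipping at the end."""
    i0 = int(round(onset_s * fs))
    if i0 >= len(series):
        return
    i1 = min(i0 + len(burst), len(series))
    series[i0:i1] += burst[: i1 - i0]


def _emg_burst(rng: np.random.Generator, fs: float, dur_s: float, amp: float) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 8)
    env = np.hanning(n)
    return amp * env * _band_noise(rng, n, fs, 20.0, 100.0)


def _ssw_packet(
    rng: np.random.Generator, fs: float, dur_s: float, amp: float, carrier_hz: float
) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 8)
    t = np.arange(n) / fs
    f = carrier_hz * rng.uniform(0.94, 1.06)
    tone = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    rough = _band_noise(rng, n, fs, 40.0, 160.0)
    return amp * np.hanning(n) * (0.8 * tone + 0.35 * rough)


def _cough_sound(rng: np.random.Generator, fs: float, dur_s: float, amp: float) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 8)
    t = np.linspace(0, 1, n)
    env = (t**0.35) * np.exp(-4.0 * t)  # fast attack, slower decay
    env /= env.max()
    return amp * env * _band_noise(rng, n, fs, 40.0, 450.0)


def _chew_click(rng: np.random.Generator, fs: float, amp: float) -> np.ndarray:
    n = max(int(round(0.05 * fs)), 8)
    return amp * np.hanning(n) * _band_noise(rng, n, fs, 60.0, 300.0)


def _realize_timing(
    template: SwallowTemplate, rng: np.random.Generator
) -> EventTruth:
    """Apply transit stretch and (for aspiration) the desync model."""
    s = template.transit_scale
    emg1_on = template.emg1_onset_s * s
    emg1_dur = template.emg1_duration_s * s
    emg2_on = template.emg2_onset_s * s
    emg2_dur = template.emg2_duration_s * s
    ssw_on = np.array(template.ssw_onsets_s) * s
    ssw_dur = np.array(template.ssw_durations_s) * s

    if template.class_label == "silent_aspiration":
        if rng.uniform() < ASPIRATION_DESYNC_PROB:
            lo, hi = ASPIRATION_DELAY_RANGE_S
            delay = rng.uniform(lo, hi)
            if rng.uniform() < 0.5 and ssw_on[0] - delay >= 0.0:
                delay = -delay
            ssw_on = ssw_on + delay
        ssw_on = ssw_on + rng.normal(0.0, template.desync_jitter_s, size=3)
        ssw_on = np.maximum(ssw_on, 0.0)

    return EventTruth(
        class_label=template.class_label,
        emg1_onset_s=float(emg1_on),
        emg1_end_s=float(emg1_on + emg1_dur),
        emg2_onset_s=float(emg2_on),
        emg2_end_s=float(emg2_on + emg2_dur),
        ssw_onsets_s=tuple(float(x) for x in ssw_on),
        ssw_ends_s=tuple(float(o + d) for o, d in zip(ssw_on, ssw_dur)),
    )


def is_sequence_coherent(truth: EventTruth) -> bool:
    """True when the realized event follows the normal-swallow grammar.

    Requires strictly increasing sound-wave onsets, the digastric burst
    leading the first sound wave, and the sternohyoid onset between the
    first and second sound waves.
    """
    o1, o2, o3 = truth.ssw_onsets_s
    return (
        o1 < o2 < o3
        and truth.emg1_onset_s <= o1 + 1e-9
        and o1 - 1e-9 <= truth.emg2_onset_s <= o2 + 1e-9
    )


def render_event(
    template: SwallowTemplate,
    fs_hz: float = DEFAULT_FS_HZ,
    seed: int = 0,
    noise: NoiseSpec = DEFAULT_NOISE,
    tail_s: float = 0.3,
) -> MultimodalRecording:
    """Render one event into a short standalone recording.

    Deterministic in ``(template, fs_hz, seed)``.  Raises ``ValueError`` when
    ``fs_hz`` is below 2000 Hz (the 10-900 Hz sound band would not be
    representable).
    """
    if fs_hz < 2000:
        raise ValueError("fs_hz must be >= 2000 so the 10-900 Hz sound band is representable")
    noise.validate()
    rng = np.random.default_rng(seed)

    truth = _realize_timing(template, rng)
    ends = [truth.emg1_end_s, truth.emg2_end_s, *truth.ssw_ends_s]
    if template.class_label == "chewing":
        ends.append(truth.emg1_onset_s + (CHEW_COUNT - 1) * CHEW_INTERVAL_S + 0.35)
    n = int(round((max(ends) + tail_s) * fs_hz))
    dur_s = n / fs_hz

    emg1 = np.zeros(n)
    emg2 = np.zeros(n)
    sound = np.zeros(n)
    lab = template.class_label
    snd_amp = _SOUND_AMPLITUDE[lab]

    if lab == "chewing":
        for k in range(CHEW_COUNT):
            on = truth.emg1_onset_s + k * CHEW_INTERVAL_S
            _place(emg1, fs_hz, on,
                   _emg_burst(rng, fs_hz, truth.emg1_end_s - truth.emg1_onset_s,
                              template.emg1_amplitude_uV))
            _place(emg2, fs_hz, on + 0.05,
                   _emg_burst(rng, fs_hz, truth.emg2_end_s - truth.emg2_onset_s,
                              template.emg2_amplitude_uV))
            _place(sound, fs_hz, on + 0.03, _chew_click(rng, fs_hz, snd_amp))
    elif lab == "cough":
        _place(emg1, fs_hz, truth.emg1_onset_s,
               _emg_burst(rng, fs_hz, truth.emg1_end_s - truth.emg1_onset_s,
                          template.emg1_amplitude_uV))
        _place(emg2, fs_hz, truth.emg2_onset_s,
               _emg_burst(rng, fs_hz, truth.emg2_end_s - truth.emg2_onset_s,
                          template.emg2_amplitude_uV))
        _place(sound, fs_hz, truth.ssw_onsets_s[0],
               _cough_sound(rng, fs_hz, truth.ssw_ends_s[0] - truth.ssw_onsets_s[0], snd_amp))
    elif lab == "rest":
        pass
    else:  # the three swallow consistencies and silent aspiration
        if template.emg1_amplitude_uV > 0:
            _place(emg1, fs_hz, truth.emg1_onset_s,
                   _emg_burst(rng, fs_hz, truth.emg1_end_s - truth.emg1_onset_s,
                              template.emg1_amplitude_uV))
        if template.emg2_amplitude_uV > 0:
            _place(emg2, fs_hz, truth.emg2_onset_s,
                   _emg_burst(rng, fs_hz, truth.emg2_end_s - truth.emg2_onset_s,
                              template.emg2_amplitude_uV))
        for on, end, carrier in zip(truth.ssw_onsets_s, truth.ssw_ends_s, _SSW_CARRIERS_HZ):
            _place(sound, fs_hz, on, _ssw_packet(rng, fs_hz, end - on, snd_amp, carrier))

    emg1 += noise.emg_white_uV * rng.standard_normal(n)
    emg2 += noise.emg_white_uV * rng.standard_normal(n)
    sound += noise.sound_white * rng.standard_normal(n)
    if noise.powerline_uV > 0:
        t = np.arange(n) / fs_hz
        phase = rng.uniform(0, 2 * np.pi)
        hum = noise.powerline_uV * np.sin(2 * np.pi * noise.powerline_hz * t + phase)
        emg1 += hum
        emg2 += hum * 0.8

    annotations = []
    if lab != "rest":
        annotations.append(
            EventAnnotation(0.0, dur_s, lab, truth=template, realized=truth)
        )
    return MultimodalRecording(emg1, emg2, sound, fs_hz, "event", annotations)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


def _event_roster(
    events_per_participant: int, class_mix: dict[str, float], rng: np.random.Generator
) -> list[str]:
    """Largest-remainder quota of event labels, then a seeded shuffle."""
    if not class_mix:
        raise ValueError("class_mix must not be empty")
    for lab, p in class_mix.items():
        validate_label(lab)
        if p < 0:
            raise ValueError("class_mix proportions must be non-negative")
    total = sum(class_mix.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"class_mix proportions must sum to 1 (got {total})")

    labs = sorted(class_mix)
    quotas = {l: class_mix[l] * events_per_participant for l in labs}
    counts = {l: int(np.floor(quotas[l])) for l in labs}
    short = events_per_participant - sum(counts.values())
    tie = {l: r for l, r in zip(labs, rng.permutation(len(labs)))}
    by_rem = sorted(labs, key=lambda l: (-(quotas[l] - counts[l]), tie[l]))
    for l in by_rem[:short]:
        counts[l] += 1
    roster = [l for l in labs for _ in range(counts[l])]
    rng.shuffle(roster)
    return roster


def _vary_template(tpl: SwallowTemplate, rng: np.random.Generator) -> SwallowTemplate:
    """Mild per-event amplitude variability (invariant-preserving)."""
    if tpl.class_label == "rest":
        return tpl
    f1 = rng.uniform(0.85, 1.15)
    f2 = rng.uniform(0.85, 1.15)
    return dataclasses.replace(
        tpl,
        emg1_amplitude_uV=tpl.emg1_amplitude_uV * f1,
        emg2_amplitude_uV=tpl.emg2_amplitude_uV * f2,
    )


def generate_session(
    n_participants: int,
    events_per_participant: int,
    class_mix: dict[str, float],
    noise: NoiseSpec = DEFAULT_NOISE,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    gap_s: float = DEFAULT_GAP_S,
    gain_range: tuple[float, float] = (0.75, 1.3),
    participant_prefix: str = "P",
) -> list[MultimodalRecording]:
    """Generate one annotated recording per participant.

    Events are drawn from ``class_mix`` (quota sampling per participant, so
    the mix is honored even for small event counts), separated by ``gap_s``
    of rest.  A per-participant gain drawn from ``gain_range`` emulates
    inter-subject signal-strength variability.  ``rest`` entries in the mix
    contribute unannotated quiet stretches.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if events_per_participant < 0:
        raise ValueError("events_per_participant must be non-negative")
    noise.validate()
    master = np.random.default_rng(seed)
    recordings = []
    for p in range(n_participants):
        prng = np.random.default_rng(master.integers(0, 2**63))
        gain = prng.uniform(*gain_range)
        roster = _event_roster(events_per_participant, class_mix, prng)

        chunks_e1: list[np.ndarray] = []
        chunks_e2: list[np.ndarray] = []
        chunks_sn: list[np.ndarray] = []
        annotations: list[EventAnnotation] = []
        t = 0.0

        def _gap(duration: float) -> None:
            nonlocal t
            n = int(round(duration * fs_hz))
            g1 = noise.emg_white_uV * prng.standard_normal(n)
            g2 = noise.emg_white_uV * prng.standard_normal(n)
            gs = noise.sound_white * prng.standard_normal(n)
            if noise.powerline_uV > 0:
                tt = np.arange(n) / fs_hz
                hum = noise.powerline_uV * np.sin(
                    2 * np.pi * noise.powerline_hz * (t + tt) + 0.1
                )
                g1 += hum
                g2 += hum * 0.8
            chunks_e1.append(gain * g1)
            chunks_e2.append(gain * g2)
            chunks_sn.append(gain * gs)
            t += n / fs_hz

        _gap(gap_s / 2)
        for lab in roster:
            if lab == "rest":
                _gap(2.0)
                _gap(gap_s)
                continue
            tpl = _vary_template(default_template(lab), prng)
            ev = render_event(tpl, fs_hz, seed=int(prng.integers(0, 2**63)), noise=noise)
            chunks_e1.append(gain * ev.emg_ch1)
            chunks_e2.append(gain * ev.emg_ch2)
            chunks_sn.append(gain * ev.sound)
            src = ev.annotations[0]
            annotations.append(
                EventAnnotation(t, t + src.end_s, lab, truth=tpl, realized=src.realized)
            )
            t += ev.duration_s
            _gap(gap_s)

        recordings.append(
            MultimodalRecording(
                np.concatenate(chunks_e1),
                np.concatenate(chunks_e2),
                np.concatenate(chunks_sn),
                fs_hz,
                f"{participant_prefix}{p + 1:03d}",
                annotations,
            )
        )
    return recordings
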