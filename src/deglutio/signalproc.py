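"""Filtering, resampling, spectrogram and SNR primitives.

All filters are zero-phase (forward-backward second-order sections), so event
timing is preserved through the preprocessing chain.  The EMG chain is a
20-100 Hz Butterworth bandpass plus a 59-61 Hz notch; the sound chain is a
10-900 Hz bandpass with an optional spectral-subtraction noise-reduction step
driven by a caller-supplied rest segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "FilterSpec",
    "SnrResult",
    "filter_emg",
    "filter_sound",
    "resample",
    "spectrogram",
    "snr_db",
    "preprocess_recording",
]


@dataclass(frozen=True)
class FilterSpec:
    emg_band_hz: tuple[float, float] = (20.0, 100.0)
    notch_band_hz: tuple[float, float] = (59.0, 61.0)
    sound_band_hz: tuple[float, float] = (10.0, 900.0)
    model_fs_hz: float = 250.0
    acquisition_fs_hz: float = 2000.0
    order: int = 4

    def __post_init__(self) -> None:
        for lo, hi in (self.emg_band_hz, self.notch_band_hz, self.sound_band_hz):
            if not 0 < lo < hi:
                raise ValueError("bands require 0 < lower < upper")
        if not 0 < self.model_fs_hz < self.acquisition_fs_hz:
            raise ValueError("model_fs_hz must be positive and below acquisition_fs_hz")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


DEFAULT_FILTER_SPEC = FilterSpec()


@dataclass(frozen=True)
class SnrResult:
    """Amplitude-ratio SNR: snr_db = 20 log10(a_signal / a_noise)."""

    a_signal: float
    a_noise: float
    snr_db: float

    def __post_init__(self) -> None:
        if self.a_signal <= 0 or self.a_noise <= 0:
            raise ValueError("amplitudes must be strictly positive")
        expected = 20.0 * np.log10(self.a_signal / self.a_noise)
        if abs(expected - self.snr_db) > 1e-9:
            raise ValueError("snr_db inconsistent with amplitude ratio")


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    return x


def filter_emg(series, fs_hz: float, spec: FilterSpec = DEFAULT_FILTER_SPEC) -> np.ndarray:
    """Bandpass (20-100 Hz) + powerline notch, zero-phase."""
    x = _as_series(series)
    lo, hi = spec.emg_band_hz
    if fs_hz <= 2 * hi:
        raise ValueError(f"fs_hz={fs_hz} too low for the {lo}-{hi} Hz EMG band")
    sos = signal.butter(spec.order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
    nlo, nhi = spec.notch_band_hz
    f0 = (nlo + nhi) / 2.0
    q = f0 / (nhi - nlo)
    b, a = signal.iirnotch(f0, q, fs=fs_hz)
    sos_notch = signal.tf2sos(b, a)
    y = signal.sosfiltfilt(sos, x)
    # apply the notch twice so the 60 Hz null survives the wide passband
    y = signal.sosfiltfilt(sos_notch, y)
    y = signal.sosfiltfilt(sos_notch, y)
    return y


def _spectral_subtract(x: np.ndarray, rest: np.ndarray, fs_hz: float,
                       floor: float = 0.05) -> np.ndarray:
    """Magnitude spectral subtraction using the rest segment as noise profile."""
    nper = min(256, len(x), len(rest))
    nper = max(nper, 16)
    win = signal.get_window("hann", nper)
    _, _, noise_stft = signal.stft(rest, fs=fs_hz, window=win, nperseg=nper)
    noise_mag = np.mean(np.abs(noise_stft), axis=1, keepdims=True)
    _, _, x_stft = signal.stft(x, fs=fs_hz, window=win, nperseg=nper)
    mag = np.abs(x_stft)
    phase = np.angle(x_stft)
    clean = np.maximum(mag - noise_mag, floor * mag)
    _, y = signal.istft(clean * np.exp(1j * phase), fs=fs_hz, window=win, nperseg=nper)
    if len(y) >= len(x):
        return y[: len(x)]
    return np.pad(y, (0, len(x) - len(y)))


def filter_sound(
    series,
    fs_hz: float,
    spec: FilterSpec = DEFAULT_FILTER_SPEC,
    rest_reference=None,
    noise_reduction: bool = True,
) -> np.ndarray:
    """10-900 Hz bandpass; spectral subtraction first when a rest reference is given."""
    x = _as_series(series)
    lo, hi = spec.sound_band_hz
    if fs_hz < 2 * hi:
        raise ValueError(f"fs_hz={fs_hz} too low: the {hi} Hz band edge is unrepresentable")
    if rest_reference is not None and noise_reduction:
        x = _spectral_subtract(x, _as_series(rest_reference), fs_hz)
    hi_eff = min(hi, 0.995 * fs_hz / 2)
    sos = signal.butter(spec.order, [lo, hi_eff], btype="bandpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def resample(series, fs_in: float, fs_out: float = 250.0) -> np.ndarray:
    """Polyphase anti-aliased resampling; output length round(n * fs_out / fs_in)."""
    x = _as_series(series)
    if fs_out <= 0 or fs_out > fs_in:
        raise ValueError("fs_out must satisfy 0 < fs_out <= fs_in")
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, padtype="line")


def spectrogram(series, fs_hz: float, window_s: float = 0.128, hop_s: float = 0.032):
    """STFT magnitude matrix: (freqs, times, |S|) with a Hann window."""
    x = _as_series(series)
    if len(x) == 0:
        raise ValueError("empty series")
    nper = int(round(window_s * fs_hz))
    if nper < 8:
        raise ValueError("window too short: need window_s * fs_hz >= 8 samples")
    hop = int(round(hop_s * fs_hz))
    if not 0 < hop <= nper:
        raise ValueError("hop_s must be positive and <= window_s")
    f, t, sxx = signal.stft(
        x, fs=fs_hz, window="hann", nperseg=nper, noverlap=nper - hop, boundary=None
    )
    return f, t, np.abs(sxx)


def snr_db(signal_segment, noise_segment, amplitude: str = "rms") -> SnrResult:
    """SNR in dB from the amplitude ratio of two segments.

    ``amplitude`` selects the definition: "rms" (default) or "peak".
    """
    s = _as_series(signal_segment)
    n = _as_series(noise_segment)
    if len(s) == 0 or len(n) == 0:
        raise ValueError("segments must be non-empty")
    if amplitude == "rms":
        a_s = float(np.sqrt(np.mean(s**2)))
        a_n = float(np.sqrt(np.mean(n**2)))
    elif amplitude == "peak":
        a_s = float(np.max(np.abs(s)))
        a_n = float(np.max(np.abs(n)))
    else:
        raise ValueError("amplitude must be 'rms' or 'peak'")
    if a_n == 0:
        raise ValueError("noise segment has zero amplitude; SNR undefined")
    if a_s == 0:
        raise ValueError("signal segment has zero amplitude; SNR undefined")
    return SnrResult(a_s, a_n, 20.0 * float(np.log10(a_s / a_n)))


def preprocess_recording(recording, spec: FilterSpec = DEFAULT_FILTER_SPEC,
                         noise_reduction: bool = False):
    """Filter both EMG channels and the sound channel, then resample to the model rate.

    Returns a new recording of the same type with fs_hz = spec.model_fs_hz and
    the original annotations (timing is preserved by the zero-phase filters).
    """
    from deglutio.simulate import MultimodalRecording

    rest_ref = None
    if noise_reduction and recording.annotations:
        first = min(a.start_s for a in recording.annotations)
        n_ref = int(first * recording.fs_hz)
        if n_ref > 64:
            rest_ref = recording.sound[:n_ref]
    e1 = filter_emg(recording.emg_ch1, recording.fs_hz, spec)
    e2 = filter_emg(recording.emg_ch2, recording.fs_hz, spec)
    sn = filter_sound(recording.sound, recording.fs_hz, spec,
                      rest_reference=rest_ref, noise_reduction=noise_reduction)
    e1 = resample(e1, recording.fs_hz, spec.model_fs_hz)
    e2 = resample(e2, recording.fs_hz, spec.model_fs_hz)
    sn = resample(sn, recording.fs_hz, spec.model_fs_hz)
    return MultimodalRecording(
        e1, e2, sn, spec.model_fs_hz, recording.participant_id, list(recording.annotations)
    )
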