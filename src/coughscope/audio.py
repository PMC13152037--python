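"""WAV audio I/O and preprocessing for cough recordings.

The preprocessing contract mirrors the front end of the classification
pipeline: every recording is loaded as a mono waveform, optionally
resampled to the working rate (16 kHz by default), peak-normalized,
chopped into fixed 3-second segments (clip long, zero-pad short), and
pre-emphasized with a first-order high-pass filter
``y[n] = x[n] - mu * x[n-1]`` (mu = 0.97 by default).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_SAMPLE_RATE = 16_000
DEFAULT_SEGMENT_S = 3.0
DEFAULT_PRE_EMPHASIS = 0.97
#: shortest trailing remainder (seconds) kept as a zero-padded segment
DEFAULT_MIN_KEEP_S = 0.5

CLASS_NAMES = ("healthy", "COPD", "lung cancer", "pneumonia", "COVID-19")


class AudioFormatError(ValueError):
    """Raised for unreadable, corrupt, or empty WAV input."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal: float samples (nominally in [-1, 1]) plus rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class Segment:
    """Fixed-length clip ready for feature extraction.

    ``samples`` always has exactly ``round(duration_s * sample_rate)``
    entries; shorter source material is zero-padded at the tail.
    """

    samples: np.ndarray
    sample_rate: int
    label: Optional[str] = None
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.label is not None and self.label not in CLASS_NAMES:
            raise ValueError(f"unknown class label {self.label!r}")

    def with_samples(self, samples: np.ndarray) -> "Segment":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def load_wav(path: str | os.PathLike, target_rate: Optional[int] = None) -> Waveform:
    """Read a RIFF/WAV file as a mono float waveform.

    Multi-channel audio is averaged to mono; integer PCM is rescaled to
    [-1, 1]. If ``target_rate`` is given and differs from the file's
    rate, the signal is polyphase-resampled.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"not a readable WAV file: {path}") from exc
    if data.size == 0:
        raise AudioFormatError(f"zero-length audio: {path}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    wav = Waveform(data, int(rate))
    if target_rate is not None and target_rate != wav.sample_rate:
        wav = resample(wav, target_rate)
    return wav


def write_wav(path: str | os.PathLike, w: Waveform, subtype: str = "pcm16") -> None:
    """Write a waveform as 16-bit PCM (default) or 32-bit float WAV."""
    if subtype == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0 - 2.0 ** -15)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif subtype == "float32":
        data = w.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(path, w.sample_rate, data)


def resample(w: Waveform, target_rate: int) -> Waveform:
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == w.sample_rate:
        return w
    g = np.gcd(int(target_rate), int(w.sample_rate))
    out = resample_poly(w.samples, target_rate // g, w.sample_rate // g)
    return Waveform(out, target_rate)


def peak_normalize(w: Waveform) -> Waveform:
    """Scale so max |sample| == 1; an all-zero signal is returned unchanged."""
    peak = np.max(np.abs(w.samples)) if len(w.samples) else 0.0
    if peak == 0.0:
        return w
    return Waveform(w.samples / peak, w.sample_rate)


def trim_silence(w: Waveform, frame_s: float = 0.025, rel_threshold: float = 0.01) -> Waveform:
    """Optional energy trimmer: drop leading/trailing frames whose RMS is
    below ``rel_threshold`` of the peak frame RMS. Off by default in the
    pipeline; a stand-in for manual endpoint editing.
    """
    n = len(w.samples)
    frame = max(1, int(round(frame_s * w.sample_rate)))
    n_frames = max(1, n // frame)
    usable = w.samples[: n_frames * frame].reshape(n_frames, frame)
    rms = np.sqrt(np.mean(usable**2, axis=1))
    peak = rms.max()
    if peak == 0:
        return w
    keep = np.nonzero(rms >= rel_threshold * peak)[0]
    if keep.size == 0:
        return w
    start = keep[0] * frame
    stop = min(n, (keep[-1] + 1) * frame)
    return Waveform(w.samples[start:stop], w.sample_rate)


def segment_audio(
    w: Waveform,
    duration_s: float = DEFAULT_SEGMENT_S,
    min_keep_s: float = DEFAULT_MIN_KEEP_S,
    label: Optional[str] = None,
    source_id: str = "",
) -> list[Segment]:
    """Chop a waveform into consecutive non-overlapping fixed-length segments.

    Long input yields multiple full windows; a trailing remainder of at
    least ``min_keep_s`` is zero-padded to full length, shorter remainders
    are dropped. Input shorter than one window yields exactly one
    zero-padded segment.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = len(w.samples)
    if n == 0:
        raise AudioFormatError("cannot segment an empty waveform")
    win = int(round(duration_s * w.sample_rate))
    min_keep = int(round(min_keep_s * w.sample_rate))
    segments: list[Segment] = []
    n_full = n // win
    for i in range(n_full):
        chunk = w.samples[i * win : (i + 1) * win]
        segments.append(Segment(chunk, w.sample_rate, label, f"{source_id}#{i}"))
    rem = n - n_full * win
    if rem > 0 and (n_full == 0 or rem >= min_keep):
        chunk = np.zeros(win)
        chunk[:rem] = w.samples[n_full * win :]
        segments.append(Segment(chunk, w.sample_rate, label, f"{source_id}#{n_full}"))
    return segments


def pre_emphasize(s: Segment, mu: float = DEFAULT_PRE_EMPHASIS, *, allow_any_mu: bool = False) -> Segment:
    """First-order high-pass filter y[n] = x[n] - mu * x[n-1], y[0] = x[0].

    ``mu`` must lie in [0.9, 1] (the conventional range for speech
    pre-emphasis) unless ``allow_any_mu`` is set.
    """
    if not allow_any_mu and not (0.9 <= mu <= 1.0):
        raise ValueError(f"pre-emphasis coefficient {mu} outside [0.9, 1]")
    x = s.samples
    if len(x) == 0:
        raise ValueError("cannot pre-emphasize an empty segment")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - mu * x[:-1]
    return s.with_samples(y)


def de_emphasize(s: Segment, mu: float = DEFAULT_PRE_EMPHASIS) -> Segment:
    """Exact inverse of :func:`pre_emphasize` (IIR y'[n] = y[n] + mu*y'[n-1])."""
    y = s.samples
    x = np.empty_like(y)
    acc = 0.0
    for i in range(len(y)):
        acc = y[i] + mu * acc
        x[i] = acc
    return s.with_samples(x)


def preprocess_waveform(
    w: Waveform,
    duration_s: float = DEFAULT_SEGMENT_S,
    mu: float = DEFAULT_PRE_EMPHASIS,
    trim: bool = False,
    label: Optional[str] = None,
    source_id: str = "",
) -> list[Segment]:
    """Full front end: (trim) -> normalize -> segment -> pre-emphasize."""
    if trim:
        w = trim_silence(w)
    w = peak_normalize(w)
    segs = segment_audio(w, duration_s, label=label, source_id=source_id)
    return [pre_emphasize(s, mu) for s in segs]
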