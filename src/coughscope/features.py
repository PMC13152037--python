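"""Spectrogram feature images from fixed-length audio segments.

A segment is split into 25 ms frames with a 10 ms hop, each frame is
Hamming-windowed, zero-padded to the FFT size (512 points) and
transformed; stacking the one-sided magnitude spectra column by column
and mapping to log-magnitude (dB) yields the grayscale time-frequency
image the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .audio import Segment

DEFAULT_FRAME_S = 0.025
DEFAULT_HOP_S = 0.010
DEFAULT_N_FFT = 512
#: magnitude floor applied before the log so dB values stay finite
EPS = 1e-10
DEFAULT_IMAGE_SIZE = 224


class FramingError(ValueError):
    pass


@dataclass(frozen=True)
class FrameMatrix:
    """Complete analysis frames of a segment, one frame per row."""

    frames: np.ndarray  # (n_frames, frame_len)
    frame_len_s: float
    hop_s: float
    sample_rate: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SpectrogramImage:
    """One-sided log-magnitude spectrogram, frequency bins x frames (dB)."""

    values: np.ndarray  # (n_fft//2 + 1, n_frames)
    freq_resolution: float  # Hz per bin
    time_resolution: float  # seconds per frame (the hop)
    n_fft: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def frame_count(n_samples: int, frame_len: int, hop: int) -> int:
    """Number of complete frames: floor((N - L) / H) + 1 for N >= L."""
    if n_samples < frame_len:
        return 0
    return (n_samples - frame_len) // hop + 1


def frame_signal(
    s: Segment, frame_len_s: float = DEFAULT_FRAME_S, hop_s: float = DEFAULT_HOP_S
) -> FrameMatrix:
    """Slice a segment into overlapping complete frames (no padding)."""
    rate = s.sample_rate
    frame_len = int(round(frame_len_s * rate))
    hop = int(round(hop_s * rate))
    n = len(s.samples)
    if n < frame_len:
        raise FramingError(f"segment of {n} samples is shorter than one {frame_len}-sample frame")
    n_frames = frame_count(n, frame_len, hop)
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameMatrix(s.samples[idx], frame_len_s, hop_s, rate)


def frame_spectrum(frame: np.ndarray, n_fft: int = DEFAULT_N_FFT) -> np.ndarray:
    """One-sided magnitude spectrum |X(k)|, k = 0..n_fft/2, of one frame.

    The frame is multiplied by a Hamming window of its own length and
    zero-padded up to ``n_fft`` before the transform.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise ValueError("frame must be one-dimensional")
    if len(frame) > n_fft:
        raise ValueError(f"frame of {len(frame)} samples exceeds n_fft={n_fft}")
    windowed = frame * np.hamming(len(frame))
    return np.abs(np.fft.rfft(windowed, n=n_fft))


def spectrogram_image(
    s: Segment,
    frame_len_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
    n_fft: int = DEFAULT_N_FFT,
) -> SpectrogramImage:
    """Stack per-frame spectra into a dB image of shape (n_fft/2+1, n_frames)."""
    fm = frame_signal(s, frame_len_s, hop_s)
    windowed = fm.frames * np.hamming(fm.frames.shape[1])[None, :]
    mags = np.abs(np.fft.rfft(windowed, n=n_fft, axis=1))  # (n_frames, bins)
    db = 20.0 * np.log10(mags + EPS)
    return SpectrogramImage(
        values=db.T,
        freq_resolution=s.sample_rate / n_fft,
        time_resolution=hop_s,
        n_fft=n_fft,
    )


def to_model_input(img: SpectrogramImage, size: int | tuple[int, int] = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Min-max normalize to [0, 1] and bilinearly resize for the network.

    A constant image (e.g. from an all-zero segment) maps to all zeros.
    """
    v = img.values
    lo, hi = v.min(), v.max()
    v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    if isinstance(size, int):
        size = (size, size)
    out = _sk_resize(v, size, order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def to_grayscale_png(img: SpectrogramImage, path: str) -> None:
    """Export as an 8-bit grayscale PNG, darker pixels = higher amplitude,
    low frequencies at the bottom of the image."""
    from PIL import Image

    v = img.values
    lo, hi = v.min(), v.max()
    norm = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    gray = np.round((1.0 - norm) * 255).astype(np.uint8)  # dark = loud
    Image.fromarray(gray[::-1, :], mode="L").save(path)


def featurize_segments(
    segments: list[Segment],
    size: int | tuple[int, int] = DEFAULT_IMAGE_SIZE,
    n_fft: int = DEFAULT_N_FFT,
    frame_len_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
) -> np.ndarray:
    """Batch helper: segments -> (n, H, W) float32 model-input images."""
    imgs = [
        to_model_input(spectrogram_image(s, frame_len_s, hop_s, n_fft), size)
        for s in segments
    ]
    return np.stack(imgs, axis=0)
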