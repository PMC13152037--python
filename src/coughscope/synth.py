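"""Synthetic cough-like audio with class-distinguishable spectral content.

The study corpus (2610 clinical recordings across five classes: healthy,
COPD, lung cancer, pneumonia, COVID-19) is private, so every pipeline
stage is exercised on synthetic stand-ins instead. Each clip is a train
of noise bursts: white noise passed through second-order resonators at
class-specific center frequencies, shaped by an exponentially decaying
envelope, over a low-level broadband noise floor. Classes differ in
their resonance layout (>= 300 Hz apart in at least one resonance), so
they are separable by construction; no claim of clinical acoustic
fidelity is made.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .audio import CLASS_NAMES, Segment, Waveform, peak_normalize, write_wav

DEFAULT_TOTAL = 2610


@dataclass(frozen=True)
class ClassSpec:
    """Acoustic recipe for one synthetic cough class."""

    name: str
    resonance_hz: tuple[float, ...]
    bandwidth_hz: tuple[float, ...]
    burst_count_range: tuple[int, int] = (2, 4)
    decay_s: float = 0.12
    noise_floor_db: float = -30.0  # broadband floor relative to burst level

    def __post_init__(self):
        if len(self.resonance_hz) != len(self.bandwidth_hz):
            raise ValueError("one bandwidth per resonance required")
        if self.burst_count_range[0] < 1 or self.burst_count_range[0] > self.burst_count_range[1]:
            raise ValueError("invalid burst_count_range")


#: Default class recipes. Resonance layouts are well separated (>= 300 Hz
#: in at least one resonance), emulating the premise that etiologies have
#: distinct spectral signatures.
DEFAULT_CLASS_SPECS: dict[str, ClassSpec] = {
    "healthy": ClassSpec("healthy", (400.0, 1600.0), (150.0, 300.0)),
    "COPD": ClassSpec("COPD", (700.0, 2600.0), (200.0, 400.0), decay_s=0.18),
    "lung cancer": ClassSpec("lung cancer", (1100.0, 3400.0), (250.0, 450.0)),
    "pneumonia": ClassSpec("pneumonia", (1900.0, 4600.0), (300.0, 500.0), decay_s=0.09),
    "COVID-19": ClassSpec("COVID-19", (2900.0, 5800.0), (350.0, 600.0)),
}

#: Harder preset: narrowed inter-class gaps so end-to-end accuracy does
#: not saturate (useful for attention-on vs attention-off comparisons).
HARD_CLASS_SPECS: dict[str, ClassSpec] = {
    "healthy": ClassSpec("healthy", (900.0, 2000.0), (350.0, 500.0)),
    "COPD": ClassSpec("COPD", (1050.0, 2150.0), (350.0, 500.0), decay_s=0.15),
    "lung cancer": ClassSpec("lung cancer", (1200.0, 2300.0), (350.0, 500.0)),
    "pneumonia": ClassSpec("pneumonia", (1350.0, 2450.0), (350.0, 500.0), decay_s=0.10),
    "COVID-19": ClassSpec("COVID-19", (1500.0, 2600.0), (350.0, 500.0)),
}

#: Per-class counts matching the printed training-set column headers of
#: the study's demographic table (total 2091).
TABLE1_COUNTS = {"COPD": 420, "lung cancer": 435, "pneumonia": 413,
                 "COVID-19": 398, "healthy": 425}


def _resonator_coeffs(freq: float, bandwidth: float, rate: int):
    """Second-order all-pole resonator (constrained two-pole bandpass)."""
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2 * np.pi * freq / rate
    a = [1.0, -2 * r * np.cos(theta), r * r]
    b = [1.0 - r]
    return b, a


def synth_cough(spec: ClassSpec, sample_rate: int = 16_000, duration_s: float = 3.0,
                seed: int = 0) -> Waveform:
    """One synthetic cough clip; deterministic for a fixed (spec, seed)."""
    nyquist = sample_rate / 2
    if any(f >= nyquist for f in spec.resonance_hz):
        raise ValueError("resonance frequency at or above Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    out = np.zeros(n)
    n_bursts = int(rng.integers(spec.burst_count_range[0], spec.burst_count_range[1] + 1))
    burst_len = int(round(min(0.6, 5 * spec.decay_s) * sample_rate))
    t = np.arange(burst_len) / sample_rate
    envelope = t / (0.01 + t) * np.exp(-t / spec.decay_s)  # fast attack, exp decay
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(1, n - burst_len)))
        excitation = rng.normal(size=burst_len)
        burst = np.zeros(burst_len)
        for freq, bw in zip(spec.resonance_hz, spec.bandwidth_hz):
            b, a = _resonator_coeffs(freq, bw, sample_rate)
            burst += lfilter(b, a, excitation)
        burst *= envelope
        peak = np.max(np.abs(burst))
        if peak > 0:
            burst /= peak
        out[start : start + burst_len] += burst
    floor_amp = 10.0 ** (spec.noise_floor_db / 20.0)
    out += floor_amp * rng.normal(size=n)
    return peak_normalize(Waveform(out, sample_rate))


@dataclass(frozen=True)
class DatasetManifest:
    frame: pd.DataFrame  # columns: file, label, subject_id, seed
    counts: dict
    config_hash: str

    def __len__(self) -> int:
        return len(self.frame)


def _sample_seed(master_seed: int, label: str, index: int) -> int:
    """Stable per-sample seed so any single file is regenerable alone."""
    digest = hashlib.sha256(f"{master_seed}:{label}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def generate_dataset(out_dir: str, total: int = DEFAULT_TOTAL, seed: int = 0,
                     class_specs: dict[str, ClassSpec] | None = None,
                     counts: dict[str, int] | None = None,
                     sample_rate: int = 16_000, duration_s: float = 3.0) -> DatasetManifest:
    """Write one WAV per sample plus a manifest CSV and a config snapshot.

    Default counts split ``total`` evenly across the five classes
    (522 each for the default 2610).
    """
    class_specs = class_specs or DEFAULT_CLASS_SPECS
    if counts is None:
        per, rem = divmod(total, len(class_specs))
        counts = {name: per + (1 if i < rem else 0)
                  for i, name in enumerate(class_specs)}
    if any(c <= 0 for c in counts.values()):
        raise ValueError("all class counts must be positive")
    os.makedirs(out_dir, exist_ok=True)
    cfg_repr = {
        "seed": seed, "sample_rate": sample_rate, "duration_s": duration_s,
        "counts": dict(counts),
        "class_specs": {k: vars(v) for k, v in class_specs.items()},
    }
    cfg_yaml = yaml.safe_dump(cfg_repr, sort_keys=True, default_flow_style=True)
    cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]
    rows = []
    for label, count in counts.items():
        spec = class_specs[label]
        slug = label.replace(" ", "_").replace("-", "_")
        for i in range(count):
            s = _sample_seed(seed, label, i)
            wav = synth_cough(spec, sample_rate, duration_s, seed=s)
            fname = f"{slug}_{i:04d}.wav"
            write_wav(os.path.join(out_dir, fname), wav)
            rows.append({"file": fname, "label": label,
                         "subject_id": f"{slug}_subj{i:04d}", "seed": s})
    frame = pd.DataFrame(rows)
    frame.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "generator_config.yaml"), "w") as fh:
        fh.write(cfg_yaml)
    return DatasetManifest(frame, dict(counts), cfg_hash)


def generate_segments(total: int, seed: int = 0,
                      class_specs: dict[str, ClassSpec] | None = None,
                      counts: dict[str, int] | None = None,
                      sample_rate: int = 16_000, duration_s: float = 3.0,
                      pre_emphasis: float = 0.97):
    """In-memory variant: preprocessed segments + integer labels.

    Skips the WAV round trip; used by tests and the experiment driver
    when no on-disk corpus is needed. Returns (segments, labels,
    class_names) with labels indexed into ``class_names``.
    """
    from .audio import pre_emphasize

    class_specs = class_specs or DEFAULT_CLASS_SPECS
    if counts is None:
        per, rem = divmod(total, len(class_specs))
        counts = {name: per + (1 if i < rem else 0)
                  for i, name in enumerate(class_specs)}
    names = list(class_specs)
    segments, labels = [], []
    for ci, label in enumerate(names):
        spec = class_specs[label]
        for i in range(counts[label]):
            s = _sample_seed(seed, label, i)
            wav = synth_cough(spec, sample_rate, duration_s, seed=s)
            lab = label if label in CLASS_NAMES else None
            seg = Segment(wav.samples, sample_rate, lab, f"{label}:{i}")
            segments.append(pre_emphasize(seg, pre_emphasis))
            labels.append(ci)
    return segments, np.asarray(labels, dtype=np.int64), names
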