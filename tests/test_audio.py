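"""Audio I/O, segmentation and pre-emphasis contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from coughscope.audio import (AudioFormatError, Segment, Waveform, de_emphasize,
                              load_wav, peak_normalize, pre_emphasize,
                              preprocess_waveform, segment_audio, trim_silence,
                              write_wav)

RATE = 16_000


class TestLoadWav:
    def test_zero_file_roundtrip(self, tmp_path):
        path = tmp_path / "z.wav"
        write_wav(path, Waveform(np.zeros(48_000), RATE))
        w = load_wav(path)
        assert len(w.samples) == 48_000
        assert w.sample_rate == RATE
        assert np.all(w.samples == 0.0)

    def test_roundtrip_within_pcm_quantization(self, tmp_path, rng):
        x = rng.uniform(-0.99, 0.99, RATE)
        path = tmp_path / "r.wav"
        write_wav(path, Waveform(x, RATE))
        w = load_wav(path)
        assert np.max(np.abs(w.samples - x)) <= 2.0 ** -15

    def test_stereo_opposite_channels_cancel(self, tmp_path, rng):
        c = (rng.uniform(-0.5, 0.5, 1000) * 32767).astype(np.int16)
        stereo = np.stack([c, -c], axis=1)
        path = tmp_path / "s.wav"
        wavfile.write(path, RATE, stereo)
        w = load_wav(path)
        assert np.allclose(w.samples, 0.0, atol=2.0 ** -15)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_wav(tmp_path / "missing.wav")

    def test_corrupt_header(self, tmp_path):
        path = tmp_path / "bad.wav"
        path.write_bytes(b"not a riff file at all")
        with pytest.raises(AudioFormatError):
            load_wav(path)

    def test_resample_on_load(self, tmp_path, rng):
        t = np.arange(8000) / 8000
        x = 0.5 * np.sin(2 * np.pi * 440 * t)
        path = tmp_path / "lo.wav"
        write_wav(path, Waveform(x, 8000))
        w = load_wav(path, target_rate=RATE)
        assert w.sample_rate == RATE
        assert len(w.samples) == 16_000


class TestPeakNormalize:
    def test_scales_to_unit_peak(self):
        w = peak_normalize(Waveform([0.5, -0.25, 0.1], RATE))
        assert np.allclose(w.samples, [1.0, -0.5, 0.2])

    def test_all_zero_unchanged(self):
        w = peak_normalize(Waveform(np.zeros(10), RATE))
        assert np.all(w.samples == 0.0)

    def test_idempotent(self, rng):
        w = Waveform(rng.normal(size=500), RATE)
        once = peak_normalize(w)
        twice = peak_normalize(once)
        assert np.allclose(once.samples, twice.samples)


class TestSegmentAudio:
    def test_exact_window_is_identity(self, rng):
        x = rng.normal(size=48_000)
        segs = segment_audio(Waveform(x, RATE))
        assert len(segs) == 1
        assert np.array_equal(segs[0].samples, x)

    def test_short_input_zero_padded(self, rng):
        x = rng.normal(size=32_000)
        segs = segment_audio(Waveform(x, RATE))
        assert len(segs) == 1
        assert len(segs[0].samples) == 48_000
        assert np.array_equal(segs[0].samples[:32_000], x)
        assert np.all(segs[0].samples[32_000:] == 0.0)

    def test_long_input_chunked_with_padded_tail(self, rng):
        x = rng.normal(size=120_000)
        segs = segment_audio(Waveform(x, RATE))
        assert len(segs) == 3
        assert np.array_equal(segs[0].samples, x[:48_000])
        assert np.array_equal(segs[1].samples, x[48_000:96_000])
        assert np.array_equal(segs[2].samples[:24_000], x[96_000:])
        assert np.all(segs[2].samples[24_000:] == 0.0)

    def test_tiny_remainder_dropped(self, rng):
        # 48000 + 1000 samples: remainder 1000 < 0.5 s -> dropped
        x = rng.normal(size=49_000)
        segs = segment_audio(Waveform(x, RATE))
        assert len(segs) == 1

    def test_reconstruction_conserves_samples(self, rng):
        x = rng.normal(size=100_000)
        segs = segment_audio(Waveform(x, RATE))
        recon = np.concatenate([s.samples for s in segs])
        n_keep = min(len(x), len(segs) * 48_000)
        assert np.array_equal(recon[:n_keep], x[:n_keep])
        for s in segs:
            assert len(s.samples) == 48_000

    def test_empty_waveform_rejected(self):
        with pytest.raises((AudioFormatError, ValueError)):
            segment_audio(Waveform(np.zeros(0), RATE))


class TestPreEmphasis:
    def test_impulse_response(self):
        s = Segment([1.0, 0.0, 0.0], RATE)
        out = pre_emphasize(s, 0.97)
        assert np.allclose(out.samples, [1.0, -0.97, 0.0])

    def test_constant_signal(self):
        out = pre_emphasize(Segment([1.0, 1.0, 1.0], RATE), 0.97)
        assert np.allclose(out.samples, [1.0, 0.03, 0.03])

    def test_zero_in_zero_out(self):
        out = pre_emphasize(Segment(np.zeros(100), RATE))
        assert np.all(out.samples == 0.0)

    def test_mu_range_enforced(self):
        s = Segment(np.ones(10), RATE)
        with pytest.raises(ValueError):
            pre_emphasize(s, 0.5)
        pre_emphasize(s, 0.5, allow_any_mu=True)  # explicit override allowed

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invertible(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        s = Segment(x, RATE)
        back = de_emphasize(pre_emphasize(s, 0.97), 0.97)
        assert np.max(np.abs(back.samples - x)) < 1e-9


def test_trim_silence_removes_padding(rng):
    body = rng.uniform(-1, 1, 8000)
    x = np.concatenate([np.zeros(4000), body, np.zeros(4000)])
    trimmed = trim_silence(Waveform(x, RATE))
    assert len(trimmed.samples) <= len(body) + 2 * 400  # one frame slack per side
    assert np.max(np.abs(trimmed.samples)) == np.max(np.abs(body))


def test_preprocess_waveform_full_chain(rng):
    x = rng.normal(size=70_000)
    segs = preprocess_waveform(Waveform(x, RATE), label="COPD", source_id="a")
    assert all(len(s.samples) == 48_000 for s in segs)
    assert all(s.label == "COPD" for s in segs)
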