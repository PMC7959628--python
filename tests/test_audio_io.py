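import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from lungsound import audio_io
from lungsound.audio_io import (
    AudioClip,
    EmptyAudioError,
    Label,
    LabelTable,
    MissingLabelError,
    fix_duration,
    label_from_diagnosis,
    load_dataset,
    read_wav,
    resample,
    write_wav,
)


class TestReadWav:
    def test_header_determines_length_and_rate(self, tmp_path):
        sr = 44_100
        data = (np.sin(2 * np.pi * 440 * np.arange(sr) / sr) * 20000).astype(np.int16)
        wavfile.write(tmp_path / "a.wav", sr, data)
        clip = read_wav(tmp_path / "a.wav")
        assert len(clip.samples) == sr
        assert clip.sample_rate == sr
        assert np.abs(clip.samples).max() <= 1.0

    def test_opposite_channels_cancel_to_silence(self, tmp_path):
        x = (np.random.default_rng(0).integers(-30000, 30000, 1000)).astype(np.int16)
        stereo = np.column_stack([x, -x])
        wavfile.write(tmp_path / "s.wav", 8000, stereo)
        clip = read_wav(tmp_path / "s.wav")
        assert np.allclose(clip.samples, 0.0, atol=1 / 32768)

    def test_roundtrip_within_16bit_quantization(self, tmp_path, rng):
        original = AudioClip(rng.uniform(-0.99, 0.99, 5000), 22_050, source_id="rt")
        write_wav(original, tmp_path / "rt.wav")
        back = read_wav(tmp_path / "rt.wav")
        assert len(back.samples) == len(original.samples)
        assert np.max(np.abs(back.samples - original.samples)) <= 2.0**-15

    def test_float32_roundtrip_is_near_exact(self, tmp_path, rng):
        original = AudioClip(rng.uniform(-1, 1, 2000), 16_000)
        write_wav(original, tmp_path / "f.wav", encoding="float32")
        back = read_wav(tmp_path / "f.wav")
        assert np.allclose(back.samples, original.samples, atol=1e-7)

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.wav"
        bad.write_bytes(b"this is not RIFF data at all....")
        with pytest.raises(audio_io.AudioIOError):
            read_wav(bad)


class TestResample:
    def test_same_rate_is_identity(self, tone_clip):
        out = resample(tone_clip, tone_clip.sample_rate)
        assert out is tone_clip

    def test_downsample_length_ratio(self, rng):
        clip = AudioClip(rng.uniform(-0.5, 0.5, 2 * 44_100), 44_100)
        out = resample(clip, 22_050)
        assert out.sample_rate == 22_050
        assert len(out.samples) == 44_100

    def test_tone_peak_survives_downsampling(self):
        sr = 44_100
        t = np.arange(2 * sr) / sr
        clip = AudioClip(0.5 * np.sin(2 * np.pi * 440 * t), sr)
        out = resample(clip, 22_050)
        freqs = np.fft.rfftfreq(len(out.samples), 1 / 22_050)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(out.samples)))]
        assert abs(peak - 440.0) <= freqs[1]  # within one FFT bin

    def test_nonpositive_rate_rejected(self, tone_clip):
        with pytest.raises(ValueError):
            resample(tone_clip, 0)


class TestFixDuration:
    def test_exact_length_clip_unchanged(self):
        sr = 22_050
        clip = AudioClip(np.ones(20 * sr) * 0.1, sr)
        out = fix_duration(clip, 20.0)
        assert len(out.samples) == 441_000
        assert np.array_equal(out.samples, clip.samples)

    def test_short_clip_zero_padded_at_tail(self):
        sr = 22_050
        clip = AudioClip(np.ones(5 * sr) * 0.2, sr)
        out = fix_duration(clip, 20.0)
        assert len(out.samples) == 441_000
        assert np.count_nonzero(out.samples == 0.0) == 330_750
        assert np.array_equal(out.samples[: 5 * sr], clip.samples)

    def test_long_clip_keeps_head(self, rng):
        sr = 22_050
        clip = AudioClip(rng.uniform(-0.5, 0.5, 90 * sr), sr)
        out = fix_duration(clip, 20.0)
        assert np.array_equal(out.samples, clip.samples[:441_000])

    @settings(max_examples=25, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=5000),
        target=st.floats(min_value=0.01, max_value=2.0),
    )
    def test_idempotent_and_rate_preserving(self, n, target):
        clip = AudioClip(np.linspace(-1, 1, n), 1000)
        once = fix_duration(clip, target)
        twice = fix_duration(once, target)
        assert np.array_equal(once.samples, twice.samples)
        assert once.sample_rate == clip.sample_rate

    def test_energy_monotonicity(self, rng):
        clip = AudioClip(rng.uniform(-1, 1, 3000), 1000)
        truncated = fix_duration(clip, 1.0)
        padded = fix_duration(clip, 5.0)
        energy = lambda c: float(np.sum(c.samples**2))
        assert energy(truncated) <= energy(clip)
        assert energy(padded) == pytest.approx(energy(clip))

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            fix_duration(AudioClip(np.ones(10), 100), -1.0)
        with pytest.raises(EmptyAudioError):
            fix_duration(AudioClip(np.zeros(0), 100), 1.0)


class TestLabels:
    @pytest.mark.parametrize(
        "diagnosis,expected",
        [
            ("COPD", Label.COPD),
            ("copd", Label.COPD),
            ("CoPd", Label.COPD),
            ("Healthy", Label.NON_COPD),
            ("URTI", Label.NON_COPD),
            ("Asthma", Label.NON_COPD),
            ("", Label.UNLABELED),
        ],
    )
    def test_binarization(self, diagnosis, expected):
        assert label_from_diagnosis(diagnosis) == expected

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("id,diagnosis\na,COPD\na,Healthy\n")
        with pytest.raises(ValueError, match="duplicate"):
            LabelTable.from_csv(p)

    def test_csv_roundtrip(self, tmp_path):
        table = LabelTable({"x": "COPD", "y": "Healthy"})
        table.to_csv(tmp_path / "l.csv")
        assert LabelTable.from_csv(tmp_path / "l.csv").entries == table.entries


class TestLoadDataset:
    def _write(self, tmp_path, ids):
        rng = np.random.default_rng(0)
        for i in ids:
            write_wav(AudioClip(rng.uniform(-0.5, 0.5, 800), 8000, source_id=i),
                      tmp_path / f"{i}.wav")

    def test_sorted_order_and_labels(self, tmp_path):
        self._write(tmp_path, ["c", "a", "b"])
        table = LabelTable({"a": "COPD", "b": "Healthy", "c": "COPD"})
        clips = load_dataset(tmp_path, table, target_rate=None)
        assert [c.source_id for c in clips] == ["a", "b", "c"]
        assert [c.label for c in clips] == [Label.COPD, Label.NON_COPD, Label.COPD]

    def test_skip_policy_drops_unlabeled(self, tmp_path):
        self._write(tmp_path, ["a", "orphan"])
        table = LabelTable({"a": "COPD"})
        clips = load_dataset(tmp_path, table, policy="skip-unlabeled", target_rate=None)
        assert [c.source_id for c in clips] == ["a"]

    def test_strict_policy_names_the_orphan(self, tmp_path):
        self._write(tmp_path, ["a", "orphan"])
        table = LabelTable({"a": "COPD"})
        with pytest.raises(MissingLabelError, match="orphan"):
            load_dataset(tmp_path, table, target_rate=None)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(audio_io.AudioIOError):
            load_dataset(tmp_path, LabelTable({}))

    def test_resamples_to_canonical_rate(self, tmp_path):
        rng = np.random.default_rng(1)
        write_wav(AudioClip(rng.uniform(-0.5, 0.5, 44_100), 44_100, source_id="hi"),
                  tmp_path / "hi.wav")
        clips = load_dataset(tmp_path, LabelTable({"hi": "COPD"}))
        assert clips[0].sample_rate == audio_io.CANONICAL_RATE
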