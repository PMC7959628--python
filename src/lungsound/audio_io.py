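"""Reading, canonicalizing and duration-normalizing lung-sound recordings.

Recordings arrive as mono or stereo WAV files of very uneven length (auscultation
corpora typically span 10-90 s per file) together with a per-recording diagnosis
table.  Everything downstream assumes a fixed analysis format: mono, float
amplitudes in [-1, 1], a canonical sample rate of 22 050 Hz and a fixed duration
of 20 s.  This module owns that normalization.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical analysis sample rate.  With hop 512 and centered frames a 20 s clip
#: yields floor(20*22050/512)+1 = 862 frames, the time extent the CNN expects.
CANONICAL_RATE = 22_050

#: Fixed clip duration in seconds; longer recordings are head-truncated, shorter
#: ones zero-padded at the tail.
CANONICAL_SECONDS = 20.0


class AudioIOError(Exception):
    """Base class for audio ingestion failures."""


class UnreadableFileError(AudioIOError):
    """The path does not parse as a RIFF/WAVE file."""


class UnsupportedEncodingError(AudioIOError):
    """The WAV encoding is not PCM or IEEE float."""


class EmptyAudioError(AudioIOError):
    """The file contains zero samples."""


class MissingLabelError(AudioIOError):
    """A recording has no entry in the label table under strict policy."""


class Label(enum.Enum):
    COPD = "COPD"
    NON_COPD = "NON_COPD"
    UNLABELED = "UNLABELED"


def label_from_diagnosis(diagnosis_raw: str) -> Label:
    """Binarize a free-text diagnosis: exactly "copd" (case-folded) is positive.

    Every other diagnosis string (Healthy, Asthma, URTI, LRTI, ...) maps to
    NON_COPD; the empty string means unlabeled.
    """
    if diagnosis_raw == "":
        return Label.UNLABELED
    return Label.COPD if diagnosis_raw.casefold() == "copd" else Label.NON_COPD


@dataclass
class AudioClip:
    """A labeled mono waveform.

    ``samples`` are float amplitudes in [-1, 1]; ``source_id`` identifies the
    recording (for synthetic clips derived by augmentation, ``parent_id`` and
    ``technique`` record provenance).
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    label: Label = Label.UNLABELED
    diagnosis_raw: str = ""
    parent_id: str | None = None
    technique: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional (mono)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "AudioClip":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class LabelTable:
    """Mapping source_id -> raw diagnosis string (each id at most once)."""

    entries: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelTable":
        """Read a headered CSV with columns ``id,diagnosis`` (UTF-8)."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = {"id", "diagnosis"} - set(df.columns)
        if missing:
            raise ValueError(f"label CSV lacks required column(s): {sorted(missing)}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate source_id(s) in label table: {dups}")
        return cls(dict(zip(df["id"], df["diagnosis"])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"id": list(self.entries), "diagnosis": list(self.entries.values())}
        ).to_csv(path, index=False)

    def label_for(self, source_id: str) -> Label:
        return label_from_diagnosis(self.entries.get(source_id, ""))

    def __contains__(self, source_id: str) -> bool:
        return source_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


# symmetric PCM scaling (matches write_wav), so a round trip errs by <= 1/2 LSB;
# the lone extreme code (-2^15) lands just below -1 and is clipped
_INT_SCALES = {np.int16: 32767.0, np.int32: 2147483647.0}


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM or float WAV file as a mono AudioClip with samples in [-1, 1].

    Multi-channel audio is averaged to mono; the header sample rate is kept.
    Raises :class:`UnreadableFileError`, :class:`UnsupportedEncodingError` or
    :class:`EmptyAudioError` for the corresponding failure modes.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except ValueError as exc:
        msg = str(exc).lower()
        if "unsupported" in msg or "unknown wave file format" in msg or "bit depth" in msg:
            raise UnsupportedEncodingError(f"{path}: {exc}") from exc
        raise UnreadableFileError(f"{path}: {exc}") from exc
    except Exception as exc:  # malformed RIFF chunks and friends
        raise UnreadableFileError(f"{path}: {exc}") from exc

    if data.size == 0:
        raise EmptyAudioError(f"{path}: zero-length audio")

    if data.dtype == np.uint8:  # 8-bit PCM is offset binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.type in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype.type]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedEncodingError(f"{path}: unsupported sample dtype {data.dtype}")

    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioClip(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(clip: AudioClip, path: str | Path, encoding: str = "pcm16") -> None:
    """Write a clip as 16-bit PCM (default) or 32-bit float WAV."""
    path = Path(path)
    x = np.clip(clip.samples, -1.0, 1.0)
    if encoding == "pcm16":
        data = np.round(x * 32767.0).astype(np.int16)
    elif encoding == "float32":
        data = x.astype(np.float32)
    else:
        raise ValueError(f"unsupported encoding {encoding!r} (use 'pcm16' or 'float32')")
    wavfile.write(path, clip.sample_rate, data)


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Polyphase resampling to ``target_rate`` Hz (duration preserved to <1 sample)."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == clip.sample_rate:
        return clip
    ratio = Fraction(target_rate, clip.sample_rate)
    out = resample_poly(clip.samples, ratio.numerator, ratio.denominator)
    out = np.clip(out, -1.0, 1.0)
    return replace(clip, samples=out, sample_rate=int(target_rate))


def fix_duration(clip: AudioClip, target_seconds: float = CANONICAL_SECONDS) -> AudioClip:
    """Trim or zero-pad to exactly round(target_seconds * sample_rate) samples.

    Longer clips keep the head of the recording; shorter clips are padded with
    zeros at the tail.  Idempotent and sample-rate preserving.
    """
    if target_seconds <= 0:
        raise ValueError(f"target_seconds must be positive, got {target_seconds}")
    if len(clip.samples) == 0:
        raise EmptyAudioError(f"{clip.source_id or '<clip>'}: empty clip")
    n_target = round(target_seconds * clip.sample_rate)
    x = clip.samples
    if len(x) >= n_target:
        out = x[:n_target]
    else:
        out = np.concatenate([x, np.zeros(n_target - len(x))])
    return clip.with_samples(out)


def load_dataset(
    audio_dir: str | Path,
    labels: LabelTable,
    *,
    policy: str = "strict",
    target_rate: int | None = CANONICAL_RATE,
) -> list[AudioClip]:
    """Load every ``*.wav`` under ``audio_dir``, labeled and in sorted-id order.

    ``policy`` is ``"strict"`` (unlabeled file -> :class:`MissingLabelError`) or
    ``"skip-unlabeled"``.  Clips are resampled to ``target_rate`` unless it is
    None.  Output order is sorted by source_id, independent of filesystem
    enumeration order.
    """
    if policy not in ("strict", "skip-unlabeled"):
        raise ValueError(f"unknown policy {policy!r}")
    audio_dir = Path(audio_dir)
    paths = sorted(audio_dir.glob("*.wav"), key=lambda p: p.stem)
    if not paths:
        raise AudioIOError(f"no .wav files found in {audio_dir}")
    clips: list[AudioClip] = []
    for p in paths:
        if p.stem not in labels:
            if policy == "strict":
                raise MissingLabelError(f"no label for recording id {p.stem!r}")
            continue
        clip = read_wav(p)
        diagnosis = labels.entries[p.stem]
        clip = replace(clip, diagnosis_raw=diagnosis, label=label_from_diagnosis(diagnosis))
        if target_rate is not None:
            clip = resample(clip, target_rate)
        clips.append(clip)
    return clips
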