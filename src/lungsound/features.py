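"""Five 40-bin time-frequency representations on a fixed 40x862 frame grid.

The classifier consumes a single-channel "image" of shape (40, 862, 1): 40
coefficient/band/pitch bins by 862 frames, the frame count of a 20 s clip at
22 050 Hz with hop 512 under centered framing.  Five feature kinds are
supported: MFCC, mel power spectrogram, and three chromagram variants (STFT,
constant-Q, CENS).  All extractors share one STFT front end (Hann window,
n_fft 2048, zero-padded centered frames) so frame counts agree across kinds.

The bin count is 40 for every kind, including the chroma features, which are
computed as octave-folded profiles with 40 bins per octave rather than the
conventional 12 pitch classes; 12-bin chroma is available by passing
``n_bins=12`` where pitch-class semantics are wanted.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.fft import dct

from .audio_io import AudioClip, EmptyAudioError

DEFAULT_HOP = 512
DEFAULT_N_FFT = 2048
DEFAULT_N_BINS = 40
TARGET_FRAMES = 862

#: Reference frequency for octave folding: C1 in 12-TET at A4 = 440 Hz.
_C1_HZ = 32.70319566257483

#: Additive guard inside log compression so silence stays well-defined.
_LOG_GUARD = 1e-10


class FeatureKind(enum.Enum):
    MFCC = "mfcc"
    MELSPECTROGRAM = "melspectrogram"
    CHROMA_STFT = "chroma_stft"
    CHROMA_CQT = "chroma_cqt"
    CHROMA_CENS = "chroma_cens"


@dataclass
class FeatureMatrix:
    """One clip's time-frequency representation: (n_bins, n_frames)."""

    kind: FeatureKind
    values: np.ndarray
    hop_length: int
    sample_rate: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix values must be 2-D (bins x frames)")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def save(self, path: str | Path) -> None:
        """Persist as headerless CSV (rows = bins) plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "kind": self.kind.value,
                    "hop_length": self.hop_length,
                    "sample_rate": self.sample_rate,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = np.atleast_2d(np.loadtxt(path, delimiter=","))
        return cls(
            kind=FeatureKind(meta["kind"]),
            values=values,
            hop_length=int(meta["hop_length"]),
            sample_rate=int(meta["sample_rate"]),
        )


def frame_count(n_samples: int, hop_length: int) -> int:
    """Number of centered frames: floor(n_samples / hop_length) + 1."""
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    if hop_length < 1:
        raise ValueError("hop_length must be >= 1")
    return n_samples // hop_length + 1


def stft_power(
    y: np.ndarray, *, n_fft: int = DEFAULT_N_FFT, hop_length: int = DEFAULT_HOP
) -> np.ndarray:
    """Power spectrogram |STFT|^2, shape (1 + n_fft//2, frame_count(len(y), hop)).

    Frames are centered: the signal is zero-padded by n_fft//2 on both sides and
    frame t covers samples around t*hop_length.  Hann window.
    """
    y = np.asarray(y, dtype=np.float64)
    pad = n_fft // 2
    ypad = np.concatenate([np.zeros(pad), y, np.zeros(pad)])
    frames = np.lib.stride_tricks.sliding_window_view(ypad, n_fft)[::hop_length]
    window = np.hanning(n_fft + 1)[:-1]  # periodic Hann
    spec = np.fft.rfft(frames * window, axis=1)
    return (spec.real**2 + spec.imag**2).T


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    sample_rate: int, n_fft: int, n_mels: int, fmin: float = 0.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank (n_mels, 1 + n_fft//2), HTK mel scale."""
    if fmax is None:
        fmax = sample_rate / 2.0
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def melspectrogram(
    y: np.ndarray,
    sample_rate: int,
    *,
    n_mels: int = DEFAULT_N_BINS,
    n_fft: int = DEFAULT_N_FFT,
    hop_length: int = DEFAULT_HOP,
) -> np.ndarray:
    power = stft_power(y, n_fft=n_fft, hop_length=hop_length)
    return mel_filterbank(sample_rate, n_fft, n_mels) @ power


def mfcc(
    y: np.ndarray,
    sample_rate: int,
    *,
    n_mfcc: int = DEFAULT_N_BINS,
    n_mels: int | None = None,
    n_fft: int = DEFAULT_N_FFT,
    hop_length: int = DEFAULT_HOP,
) -> np.ndarray:
    """MFCCs: orthonormal DCT-II of the log mel power spectrogram.

    With the default 40 mel bands and 40 coefficients the DCT is square, so the
    representation is a lossless rotation of the log-mel spectrum.
    """
    if n_mels is None:
        n_mels = n_mfcc
    mel = melspectrogram(y, sample_rate, n_mels=n_mels, n_fft=n_fft, hop_length=hop_length)
    return dct(np.log(mel + _LOG_GUARD), type=2, norm="ortho", axis=0)[:n_mfcc]


def _fold_to_chroma(freqs: np.ndarray, n_chroma: int) -> np.ndarray:
    """Octave-folded bin index for each frequency (C1 reference)."""
    return np.round(n_chroma * np.log2(freqs / _C1_HZ)).astype(int) % n_chroma


def _max_normalize(c: np.ndarray) -> np.ndarray:
    peak = c.max(axis=0, keepdims=True)
    return np.where(peak > 0, c / np.maximum(peak, 1e-30), 0.0)


def chroma_stft(
    y: np.ndarray,
    sample_rate: int,
    *,
    n_chroma: int = DEFAULT_N_BINS,
    n_fft: int = DEFAULT_N_FFT,
    hop_length: int = DEFAULT_HOP,
) -> np.ndarray:
    """Octave-folded STFT energy profile, per-frame max-normalized to [0, 1]."""
    power = stft_power(y, n_fft=n_fft, hop_length=hop_length)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fold = np.zeros((n_chroma, power.shape[0]))
    valid = freqs > 0
    fold[_fold_to_chroma(freqs[valid], n_chroma), np.nonzero(valid)[0]] = 1.0
    return _max_normalize(fold @ power)


def _pseudo_cqt(
    y: np.ndarray, sample_rate: int, *, bins_per_octave: int, n_fft: int, hop_length: int
) -> np.ndarray:
    """Constant-Q-spaced log-frequency spectrogram approximated from the STFT.

    Center frequencies are geometric from C1 at ``bins_per_octave`` per octave
    up to Nyquist; each CQT bin collects FFT power with a triangular weight one
    CQT-bin spacing wide in log2 frequency.
    """
    power = stft_power(y, n_fft=n_fft, hop_length=hop_length)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    n_octaves = int(np.floor(np.log2((sample_rate / 2.0) / _C1_HZ)))
    n_bins = n_octaves * bins_per_octave
    centers_log2 = np.log2(_C1_HZ) + np.arange(n_bins) / bins_per_octave
    log_freqs = np.full_like(freqs, -np.inf)
    log_freqs[freqs > 0] = np.log2(freqs[freqs > 0])
    width = 1.0 / bins_per_octave
    weight = np.maximum(0.0, 1.0 - np.abs(log_freqs[None, :] - centers_log2[:, None]) / width)
    return weight @ power


def chroma_cqt(
    y: np.ndarray,
    sample_rate: int,
    *,
    n_chroma: int = DEFAULT_N_BINS,
    n_fft: int = DEFAULT_N_FFT,
    hop_length: int = DEFAULT_HOP,
) -> np.ndarray:
    """Octave-folded pseudo-CQT profile, per-frame max-normalized to [0, 1]."""
    cqt = _pseudo_cqt(
        y, sample_rate, bins_per_octave=n_chroma, n_fft=n_fft, hop_length=hop_length
    )
    n_octaves = cqt.shape[0] // n_chroma
    folded = cqt.reshape(n_octaves, n_chroma, -1).sum(axis=0)
    return _max_normalize(folded)


#: CENS quantization: L1-normalized chroma energy is mapped through these
#: thresholds, each step contributing 1/4, giving values in {0, .25, .5, .75, 1}.
_CENS_STEPS = (0.05, 0.1, 0.2, 0.4)

#: Temporal smoothing window length in frames (downsampling factor 1).
_CENS_WINDOW = 41


def chroma_cens(
    y: np.ndarray,
    sample_rate: int,
    *,
    n_chroma: int = DEFAULT_N_BINS,
    n_fft: int = DEFAULT_N_FFT,
    hop_length: int = DEFAULT_HOP,
) -> np.ndarray:
    """Chroma energy normalized statistics: quantized, smoothed, unit-norm chroma.

    Pipeline: pseudo-CQT chroma -> per-frame L1 normalization -> 4-step
    quantization -> Hann smoothing over 41 frames -> per-frame L2 normalization.
    Robust to dynamics (invariant to waveform gain) and to local articulation.
    """
    cqt = _pseudo_cqt(
        y, sample_rate, bins_per_octave=n_chroma, n_fft=n_fft, hop_length=hop_length
    )
    n_octaves = cqt.shape[0] // n_chroma
    chroma = cqt.reshape(n_octaves, n_chroma, -1).sum(axis=0)
    l1 = chroma.sum(axis=0, keepdims=True)
    chroma = np.where(l1 > 0, chroma / np.maximum(l1, 1e-30), 0.0)
    quant = np.zeros_like(chroma)
    for step in _CENS_STEPS:
        quant += 0.25 * (chroma > step)
    win = np.hanning(_CENS_WINDOW + 2)[1:-1]
    half = _CENS_WINDOW // 2
    padded = np.pad(quant, ((0, 0), (half, half)), mode="constant")
    smoothed = np.stack(
        [np.convolve(row, win, mode="valid") for row in padded]
    )
    norm = np.linalg.norm(smoothed, axis=0, keepdims=True)
    return np.where(norm > 0, smoothed / np.maximum(norm, 1e-30), 0.0)


_EXTRACTORS = {
    FeatureKind.MFCC: mfcc,
    FeatureKind.MELSPECTROGRAM: melspectrogram,
    FeatureKind.CHROMA_STFT: chroma_stft,
    FeatureKind.CHROMA_CQT: chroma_cqt,
    FeatureKind.CHROMA_CENS: chroma_cens,
}

_BIN_KWARG = {
    FeatureKind.MFCC: "n_mfcc",
    FeatureKind.MELSPECTROGRAM: "n_mels",
    FeatureKind.CHROMA_STFT: "n_chroma",
    FeatureKind.CHROMA_CQT: "n_chroma",
    FeatureKind.CHROMA_CENS: "n_chroma",
}


def extract(
    clip: AudioClip,
    kind: FeatureKind,
    n_bins: int = DEFAULT_N_BINS,
    *,
    n_fft: int = DEFAULT_N_FFT,
    hop_length: int = DEFAULT_HOP,
) -> FeatureMatrix:
    """Compute one feature kind for a clip: (n_bins, floor(n/hop)+1) matrix."""
    if len(clip.samples) == 0:
        raise EmptyAudioError(f"{clip.source_id or '<clip>'}: empty clip")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not isinstance(kind, FeatureKind):
        raise ValueError(f"unknown feature kind {kind!r}")
    fn = _EXTRACTORS[kind]
    values = fn(
        clip.samples,
        clip.sample_rate,
        **{_BIN_KWARG[kind]: n_bins},
        n_fft=n_fft,
        hop_length=hop_length,
    )
    return FeatureMatrix(
        kind=kind, values=values, hop_length=hop_length, sample_rate=clip.sample_rate
    )


def pad_to_frames(m: FeatureMatrix, target_frames: int = TARGET_FRAMES) -> FeatureMatrix:
    """Right-pad with zeros (or right-truncate) to exactly ``target_frames`` columns."""
    if target_frames < 1:
        raise ValueError("target_frames must be >= 1")
    v = m.values
    if v.shape[1] >= target_frames:
        out = v[:, :target_frames]
    else:
        out = np.concatenate(
            [v, np.zeros((v.shape[0], target_frames - v.shape[1]))], axis=1
        )
    return replace(m, values=out)
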