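"""Seeded two-class synthetic lung-sound simulator.

Generates recordings with the statistical shape the pipeline assumes so every
stage is exercisable without downloading a corpus: variable clip lengths
(10-90 s), breath-cycle periodicity, and — in the positive (COPD) class —
adventitious components in the standard acoustic caricature: a tonal wheeze
(fundamental plus one harmonic) gated to the expiratory half of each cycle,
and short exponentially damped crackle impulses placed by a Poisson process.

The normal-class signal is band-limited noise (100-2000 Hz, the energetic band
of chest-wall breath sounds) amplitude-modulated by a squared-sine breath
envelope, plus broadband sensor noise.  The default class mix is 4:1
COPD:non-COPD, matching the imbalance the augmentation stage exists to fix.

This is a caricature, not physiology: it makes the two classes separable by
their spectra, which is the property the pipeline tests need.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioClip, Label, LabelTable, write_wav

_BREATH_BAND = (100.0, 2000.0)
_BREATH_RMS = 0.08  # target RMS of the modulated breath component


@dataclass
class SyntheticSpec:
    """Generator parameters; all randomness flows from ``rng_seed``."""

    n_clips: int = 50
    copd_fraction: float = 0.8
    duration_range: tuple[float, float] = (10.0, 90.0)
    sample_rate: int = 22_050
    cycle_range: tuple[float, float] = (2.5, 5.0)
    wheeze_freq_range: tuple[float, float] = (100.0, 1000.0)
    wheeze_snr_db: float = 6.0
    crackle_rate: float = 2.0
    noise_level: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.copd_fraction < 1):
            raise ValueError("copd_fraction must be strictly between 0 and 1")
        for name in ("duration_range", "cycle_range", "wheeze_freq_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.n_clips < 2:
            raise ValueError("n_clips must be >= 2")


def _bandlimited_noise(n: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    sos = butter(4, [_BREATH_BAND[0] / nyq, _BREATH_BAND[1] / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, white)


def breath_envelope(n: int, cycle_seconds: float, sample_rate: int) -> np.ndarray:
    """Squared-sine breathing envelope with period ``cycle_seconds``."""
    t = np.arange(n) / sample_rate
    return np.sin(np.pi * t / cycle_seconds) ** 2


def expiratory_gate(n: int, cycle_seconds: float, sample_rate: int, ramp_ms: float = 10.0) -> np.ndarray:
    """1 during the expiratory half of each cycle, 0 otherwise, with short ramps."""
    t = np.arange(n) / sample_rate
    phase = (t % cycle_seconds) / cycle_seconds
    gate = (phase >= 0.5).astype(np.float64)
    ramp = max(1, int(ramp_ms / 1000.0 * sample_rate))
    kernel = np.ones(ramp) / ramp
    return np.convolve(gate, kernel, mode="same")


def gen_breath(
    clip_seconds: float,
    cycle_seconds: float,
    rng: np.random.Generator,
    *,
    sample_rate: int = 22_050,
    noise_level: float = 0.1,
    amplitude: float = 1.0,
) -> AudioClip:
    """Normal-class clip: band-limited noise shaped by a breath envelope.

    ``noise_level`` is the broadband sensor-noise RMS relative to the breath
    component's RMS; ``amplitude`` scales the whole clip (0 gives silence when
    noise_level is also 0).
    """
    if clip_seconds <= 0 or cycle_seconds <= 0:
        raise ValueError("durations must be positive")
    n = round(clip_seconds * sample_rate)
    breath = _bandlimited_noise(n, sample_rate, rng) * breath_envelope(
        n, cycle_seconds, sample_rate
    )
    rms = np.sqrt(np.mean(breath**2))
    if rms > 0:
        breath *= _BREATH_RMS / rms
    noise = rng.standard_normal(n) * (noise_level * _BREATH_RMS)
    samples = amplitude * (breath + noise)
    peak = np.abs(samples).max() if n else 0.0
    if peak > 0.99:
        samples *= 0.99 / peak
    return AudioClip(
        samples=samples, sample_rate=sample_rate, label=Label.NON_COPD, diagnosis_raw="Healthy"
    )


def _crackle(duration_s: float, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """One exponentially damped impulse, 5-15 ms long."""
    n = max(2, round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    f = rng.uniform(200.0, 800.0)
    tau = duration_s / 5.0
    return np.exp(-t / tau) * np.sin(2 * np.pi * f * t)


def gen_copd(
    clip_seconds: float,
    cycle_seconds: float,
    wheeze_freq: float,
    wheeze_snr_db: float,
    crackle_rate: float,
    rng: np.random.Generator,
    *,
    sample_rate: int = 22_050,
    noise_level: float = 0.1,
    amplitude: float = 1.0,
) -> AudioClip:
    """Positive-class clip: breath plus expiratory wheeze and Poisson crackles.

    The wheeze (fundamental + one harmonic at half amplitude) is gated to the
    expiratory half of each cycle with its RMS set ``wheeze_snr_db`` decibels
    above the breath RMS in those segments; ``wheeze_snr_db=-inf`` disables it.
    Crackle count is Poisson with mean ``crackle_rate`` per breath cycle.
    """
    base = gen_breath(
        clip_seconds,
        cycle_seconds,
        rng,
        sample_rate=sample_rate,
        noise_level=noise_level,
        amplitude=amplitude,
    )
    n = len(base.samples)
    t = np.arange(n) / sample_rate
    samples = base.samples.copy()

    gate = expiratory_gate(n, cycle_seconds, sample_rate)
    gated_idx = gate > 0.5
    if math.isfinite(wheeze_snr_db) and gated_idx.any():
        breath_rms = np.sqrt(np.mean(samples[gated_idx] ** 2))
        phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
        tone = np.sin(2 * np.pi * wheeze_freq * t + phi1) + 0.5 * np.sin(
            2 * np.pi * 2 * wheeze_freq * t + phi2
        )
        tone_rms = np.sqrt(np.mean(tone[gated_idx] ** 2))
        target = breath_rms * 10.0 ** (wheeze_snr_db / 20.0)
        samples = samples + gate * tone * (target / max(tone_rms, 1e-12))

    n_cycles = clip_seconds / cycle_seconds
    n_events = int(rng.poisson(crackle_rate * n_cycles)) if crackle_rate > 0 else 0
    for _ in range(n_events):
        dur = rng.uniform(0.005, 0.015)
        burst = _crackle(dur, sample_rate, rng)
        start = int(rng.integers(0, max(1, n - len(burst))))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        samples[start : start + len(burst)] += sign * 0.5 * burst

    peak = np.abs(samples).max()
    if peak > 0.99:
        samples *= 0.99 / peak
    return AudioClip(
        samples=samples, sample_rate=sample_rate, label=Label.COPD, diagnosis_raw="COPD"
    )


def gen_dataset(spec: SyntheticSpec) -> tuple[list[AudioClip], LabelTable]:
    """Generate round(n * copd_fraction) COPD clips and the rest non-COPD.

    Deterministic under ``spec.rng_seed``; per-clip child seeds keep each clip
    reproducible independent of generation order.
    """
    n_copd = round(spec.n_clips * spec.copd_fraction)
    n_non = spec.n_clips - n_copd
    if n_copd == 0 or n_non == 0:
        raise ValueError(
            f"degenerate class mix: {n_copd} COPD / {n_non} non-COPD from "
            f"n_clips={spec.n_clips}, copd_fraction={spec.copd_fraction}"
        )
    children = np.random.SeedSequence(spec.rng_seed).spawn(spec.n_clips)
    clips: list[AudioClip] = []
    table = LabelTable()
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        duration = rng.uniform(*spec.duration_range)
        cycle = rng.uniform(*spec.cycle_range)
        is_copd = i < n_copd
        if is_copd:
            wheeze_freq = rng.uniform(*spec.wheeze_freq_range)
            clip = gen_copd(
                duration,
                cycle,
                wheeze_freq,
                spec.wheeze_snr_db,
                spec.crackle_rate,
                rng,
                sample_rate=spec.sample_rate,
                noise_level=spec.noise_level,
            )
            source_id = f"synth-{i:04d}-copd"
        else:
            clip = gen_breath(
                duration,
                cycle,
                rng,
                sample_rate=spec.sample_rate,
                noise_level=spec.noise_level,
            )
            source_id = f"synth-{i:04d}-normal"
        clip.source_id = source_id
        table.entries[source_id] = clip.diagnosis_raw
        clips.append(clip)
    return clips, table


def write_fixture(
    clips: list[AudioClip], table: LabelTable, out_dir: str | Path, spec: SyntheticSpec | None = None
) -> Path:
    """Write a self-contained fixture: WAVs + labels.csv (+ spec.json)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for clip in clips:
        write_wav(clip, out_dir / f"{clip.source_id}.wav")
    table.to_csv(out_dir / "labels.csv")
    if spec is not None:
        (out_dir / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
    return out_dir
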