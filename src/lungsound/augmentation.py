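"""Waveform augmentation operators and the class-balancing policy.

Auscultation corpora are heavily imbalanced — roughly four COPD recordings for
every non-COPD one — so the minority class is grown with label-preserving
waveform transformations until the two classes have equal counts.  Four
operators are used, cycling in a fixed order: random gain (loudness), random
time masking, circular time shift, and speed change by resampling.

All augmentation happens on raw audio, before feature extraction, because two
of the four operators (speed, loudness) are waveform-domain by nature; masking
is kept in the waveform domain for consistency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .audio_io import AudioClip, CANONICAL_SECONDS, fix_duration


class Technique(enum.Enum):
    LOUDNESS = "loudness"
    MASK = "mask"
    SHIFT = "shift"
    SPEED = "speed"


@dataclass
class AugmentationSpec:
    """Parameter ranges for the four operators.

    ``loudness_range`` is a multiplicative gain interval; ``speed_range`` a
    playback-rate interval; masking zeroes ``mask_regions`` disjoint intervals
    of ``mask_fraction`` of the clip each.
    """

    loudness_range: tuple[float, float] = (0.6, 1.4)
    mask_regions: int = 2
    mask_fraction: float = 0.05
    speed_range: tuple[float, float] = (0.5, 2.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.loudness_range[0] <= self.loudness_range[1]):
            raise ValueError(f"invalid loudness_range {self.loudness_range}")
        if not (0 < self.speed_range[0] <= self.speed_range[1]):
            raise ValueError(f"invalid speed_range {self.speed_range}")
        if not (0 < self.mask_fraction < 1):
            raise ValueError(f"mask_fraction must be in (0, 1), got {self.mask_fraction}")
        if self.mask_regions < 1:
            raise ValueError("mask_regions must be >= 1")


def augment_loudness(clip: AudioClip, factor: float) -> AudioClip:
    """Multiply samples by ``factor`` and clip to [-1, 1]."""
    if factor <= 0:
        raise ValueError(f"loudness factor must be positive, got {factor}")
    return clip.with_samples(np.clip(clip.samples * factor, -1.0, 1.0))


def augment_mask(
    clip: AudioClip,
    n_regions: int,
    region_fraction: float,
    rng: np.random.Generator,
) -> AudioClip:
    """Zero out ``n_regions`` disjoint random intervals of ``region_fraction`` each.

    Placement uses the classic gap construction (sorted uniform draws over the
    free budget), so regions are disjoint by construction.
    """
    n = len(clip.samples)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    region_len = max(1, round(region_fraction * n))
    free = n - n_regions * region_len
    if free < 0:
        raise ValueError(
            f"cannot place {n_regions} disjoint regions of {region_len} samples in {n}"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=n_regions))
    out = clip.samples.copy()
    for i, off in enumerate(offsets):
        start = int(off) + i * region_len
        out[start : start + region_len] = 0.0
    return clip.with_samples(out)


def augment_shift(
    clip: AudioClip, rng: np.random.Generator, offset: int | None = None
) -> AudioClip:
    """Circular rotation by a random offset in [-len/2, +len/2] (value-preserving)."""
    n = len(clip.samples)
    if n == 0:
        raise ValueError("cannot shift an empty clip")
    if offset is None:
        offset = int(rng.integers(-(n // 2), n // 2 + 1))
    return clip.with_samples(np.roll(clip.samples, offset))


def augment_speed(
    clip: AudioClip,
    rate: float,
    *,
    target_seconds: float | None = CANONICAL_SECONDS,
) -> AudioClip:
    """Resampling-based speed change: duration scales by 1/rate, pitch by rate.

    When ``target_seconds`` is set (the default), the stretched clip is
    trimmed/padded back to that duration so downstream shapes stay stable;
    pass ``target_seconds=None`` to get the raw stretched waveform.
    """
    if rate <= 0:
        raise ValueError(f"speed rate must be positive, got {rate}")
    frac = Fraction(rate).limit_denominator(1000)
    # playing back at `rate` keeps the sample grid but shortens the waveform:
    # resample len n -> round(n / rate) samples at the same nominal rate
    out = resample_poly(clip.samples, frac.denominator, frac.numerator)
    out = np.clip(out, -1.0, 1.0)
    stretched = clip.with_samples(out)
    if target_seconds is None:
        return stretched
    return fix_duration(stretched, target_seconds)


_CYCLE = (Technique.LOUDNESS, Technique.MASK, Technique.SHIFT, Technique.SPEED)


def apply_technique(
    clip: AudioClip,
    technique: Technique,
    spec: AugmentationSpec,
    rng: np.random.Generator,
) -> AudioClip:
    """Apply one operator with parameters drawn from ``spec``'s ranges."""
    if technique is Technique.LOUDNESS:
        factor = rng.uniform(*spec.loudness_range)
        return augment_loudness(clip, factor)
    if technique is Technique.MASK:
        return augment_mask(clip, spec.mask_regions, spec.mask_fraction, rng)
    if technique is Technique.SHIFT:
        return augment_shift(clip, rng)
    if technique is Technique.SPEED:
        rate = rng.uniform(*spec.speed_range)
        return augment_speed(clip, rate)
    raise ValueError(f"unknown technique {technique!r}")


def balance_classes(
    clips: list[AudioClip], spec: AugmentationSpec
) -> list[AudioClip]:
    """Grow the minority class with augmented copies until class counts are equal.

    Originals are always retained; only minority-class clips are augmented, and
    every synthetic clip records its parent source_id and technique.  With a
    fixed ``spec.rng_seed`` the output is deterministic.
    """
    from .audio_io import Label

    by_class: dict[Label, list[AudioClip]] = {Label.COPD: [], Label.NON_COPD: []}
    for c in clips:
        if c.label not in by_class:
            raise ValueError(f"clip {c.source_id!r} is unlabeled")
        by_class[c.label].append(c)
    n_copd, n_non = len(by_class[Label.COPD]), len(by_class[Label.NON_COPD])
    if n_copd == 0 or n_non == 0:
        raise ValueError(f"both classes must be non-empty (COPD={n_copd}, non-COPD={n_non})")
    if n_copd == n_non:
        return list(clips)
    minority = by_class[Label.COPD] if n_copd < n_non else by_class[Label.NON_COPD]
    deficit = abs(n_copd - n_non)
    rng = np.random.default_rng(spec.rng_seed)
    out = list(clips)
    for i in range(deficit):
        parent = minority[i % len(minority)]
        technique = _CYCLE[i % len(_CYCLE)]
        aug = apply_technique(parent, technique, spec, rng)
        out.append(
            replace(
                aug,
                source_id=f"{parent.source_id}__aug{i:03d}_{technique.value}",
                parent_id=parent.source_id,
                technique=technique.value,
            )
        )
    return out
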