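import numpy as np
import pytest

from lungsound.audio_io import AudioClip, Label
from lungsound.synthetic_data import SyntheticSpec, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tone_clip():
    """2 s pure 440 Hz tone at the canonical rate."""
    sr = 22_050
    t = np.arange(2 * sr) / sr
    return AudioClip(0.5 * np.sin(2 * np.pi * 440.0 * t), sr, source_id="tone440")


@pytest.fixture(scope="session")
def breath_clip():
    """One 20 s synthetic normal-class clip (4 s breath cycles)."""
    from lungsound.synthetic_data import gen_breath

    return gen_breath(20.0, 4.0, np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_dataset():
    """12 labeled clips (10-15 s) with the 4:1-ish class mix, cheap to process."""
    spec = SyntheticSpec(
        n_clips=12, copd_fraction=0.75, duration_range=(10.0, 15.0), rng_seed=3
    )
    clips, table = gen_dataset(spec)
    return clips, table, spec


def make_labeled_clip(label: Label, seconds: float = 1.0, sr: int = 8000, seed: int = 0):
    """Tiny random labeled clip for tests that only care about bookkeeping."""
    rng = np.random.default_rng(seed)
    return AudioClip(
        0.1 * rng.standard_normal(round(seconds * sr)),
        sr,
        source_id=f"clip-{label.value.lower()}-{seed:03d}",
        label=label,
        diagnosis_raw="COPD" if label == Label.COPD else "Healthy",
    )
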