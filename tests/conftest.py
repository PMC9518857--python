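import numpy as np
import pytest

from speechscreen.audio_io import AudioClip
from speechscreen.mfcc import ExtractionParams, FeatureDataset, FeatureSegment
from speechscreen.synth import CohortSpec, generate_cohort
from speechscreen.training import extract_features, split_participants


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_clip():
    sr = 44100
    t = np.arange(sr) / sr
    return AudioClip(samples=0.8 * np.sin(2 * np.pi * 440 * t), sample_rate=sr,
                     source_id="sine440")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """10 participants, 1.5 s clips at 16 kHz — cheap shared audio fixture."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_participants=10, prevalence=0.3, effect_size=1.0,
                      clip_duration_s=1.5, sample_rate=16000, seed=7)
    records, manifest = generate_cohort(spec, out)
    return records, manifest


@pytest.fixture(scope="session")
def small_features(small_cohort):
    records, _ = small_cohort
    params = ExtractionParams(n_mels=40, frames_per_segment=12, hop_length=256)
    return extract_features(records, params)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    records, _ = small_cohort
    return split_participants(records, seed=3)


def make_toy_dataset(n_per_class=12, frames=8, n_mfcc=13, sep=2.0, seed=0,
                     participants_per_class=4):
    """Gaussian feature segments with a class mean shift: fast, separable."""
    rng = np.random.default_rng(seed)
    segments = []
    for label in (0, 1):
        shift = sep * label
        for i in range(n_per_class):
            pid = f"c{label}_{i % participants_per_class}"
            feats = rng.normal(loc=shift, scale=1.0, size=(frames, n_mfcc))
            segments.append(FeatureSegment(features=feats, label=label, participant_id=pid))
    return FeatureDataset(segments=segments,
                          extraction_params=ExtractionParams(frames_per_segment=frames))
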