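import numpy as np
import pytest

from ecgid import SubjectMorphology, synthesize_ecg


@pytest.fixture
def clean_morph() -> SubjectMorphology:
    """Noise-free, jitter-free morphology with exact dyadic beat spacing."""
    return SubjectMorphology(noise_sd=0.0, baseline_amp=0.0, rr_sd=0.0, rr_mean=0.8)


@pytest.fixture
def clean_record(clean_morph):
    """60 s noiseless synthetic record with ground-truth R indices."""
    return synthesize_ecg(clean_morph, duration=60.0, fs=250.0, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
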