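import numpy as np
import pytest

from voicescreen.audio import AudioClip, PIPELINE_RATE
from voicescreen.ingest import STD_SAMPLES, StandardClip
from voicescreen.synth import SpeechProfile, ad_profile, control_profile


@pytest.fixture(scope="session")
def tone_clip():
    """1 kHz tone, 1.5 s, pipeline rate."""
    t = np.arange(int(1.5 * PIPELINE_RATE)) / PIPELINE_RATE
    return AudioClip(0.4 * np.sin(2 * np.pi * 1000 * t))


@pytest.fixture(scope="session")
def std_tone(tone_clip):
    from voicescreen.ingest import standardize_clip

    return standardize_clip(tone_clip)


@pytest.fixture(scope="session")
def silence_std():
    return StandardClip(np.zeros(STD_SAMPLES), responded=False)


@pytest.fixture(scope="session")
def profiles():
    return {"AD": ad_profile(), "control": control_profile()}


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """4/class cohort shared across feature/pipeline tests."""
    from voicescreen.synth import EffectConfig, make_cohort

    out = tmp_path_factory.mktemp("cohort")
    manifest = make_cohort(4, EffectConfig(), seed=11, out_dir=out)
    return manifest, out
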