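import numpy as np
import pytest

from nrlab.audio import gen_speech_shaped_noise, gen_target_token, mix_at_snr

FS_AUDIO = 44100.0


@pytest.fixture(scope="session")
def trial_stimulus():
    """One reference trial: 0.5 s token inside 1.5 s speech-shaped noise, 0 dB."""
    token = gen_target_token(0.5, FS_AUDIO, seed=7)
    noise = gen_speech_shaped_noise(1.5, FS_AUDIO, seed=1007)
    return mix_at_snr(token, noise, 0.0, 0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
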