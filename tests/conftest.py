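import numpy as np
import pytest

from rbhvoice.f0 import analyze_track
from rbhvoice.synthgen import VoiceSpec, synth_voice


def make_voice(n_words=17, f0=100.0, jitter=0.0, shimmer=0.0, snr=None, seed=1):
    plan = [(f"wort{k}", 0.3, 0.12) for k in range(n_words)]
    return synth_voice(VoiceSpec(word_plan=plan, f0_contour=f0,
                                 jitter_pct=jitter, shimmer_pct=shimmer,
                                 noise_snr_db=snr, seed=seed))


@pytest.fixture(scope="session")
def clean_voice():
    """17-word noise-free recording at 100 Hz with zero perturbation."""
    rec, ali = make_voice()
    track = analyze_track(rec)
    return rec, ali, track


@pytest.fixture(scope="session")
def perturbed_voice():
    """17-word recording with 2 % jitter, 5 % shimmer, 30 dB noise floor."""
    rec, ali = make_voice(jitter=2.0, shimmer=5.0, snr=30.0, seed=1)
    track = analyze_track(rec)
    return rec, ali, track


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
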