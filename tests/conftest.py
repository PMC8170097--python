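import numpy as np
import pytest

from speechmarkers import load_lexicon, parse_chat
from speechmarkers.ingest import Waveform

#: the worked-example picture description used throughout the docs
EXAMPLE_TEXT = ("*PAR:\tThere is a boy . The boy is a brother . "
                "He is stealing a cookie . The sister is watching .")


@pytest.fixture(scope="session")
def en_lexicon():
    return load_lexicon(language="en")


@pytest.fixture(scope="session")
def fr_lexicon():
    return load_lexicon(language="fr")


@pytest.fixture()
def example_transcript():
    return parse_chat(EXAMPLE_TEXT)


def make_tone(freq: float, duration: float = 3.0, rate: int = 16000,
              amplitude: float = 0.5) -> Waveform:
    t = np.arange(int(duration * rate)) / rate
    return Waveform(amplitude * np.sin(2 * np.pi * freq * t), rate)


def make_bursts(n_bursts: int = 5, duration: float = 5.0,
                rate: int = 16000) -> Waveform:
    """Amplitude-modulated vowel-like bursts, evenly spaced."""
    x = np.zeros(int(duration * rate))
    burst_len = int(0.25 * rate)
    seg = np.arange(burst_len)
    env = np.hanning(burst_len)
    for k in range(n_bursts):
        c = int((k + 0.5) * duration / n_bursts * rate)
        x[c:c + burst_len] += env * 0.5 * np.sin(2 * np.pi * 150 * seg / rate)
    return Waveform(x, rate)
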