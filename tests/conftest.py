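import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from vococoord.synthetic import make_vocalization
from vococoord.types import Waveform


@pytest.fixture(scope="session")
def vowel():
    """A 1 s synthetic vowel: 220 Hz source, 500/1500/2500 Hz resonances."""
    return make_vocalization(
        1.0, f0_contour=220.0, formant_freqs=(500.0, 1500.0, 2500.0),
        rate_hz=16000.0, seed=0,
    )


@pytest.fixture(scope="session")
def noise_wave():
    """1 s of seeded white noise at 16 kHz."""
    rng = np.random.default_rng(42)
    return Waveform(samples=0.5 * rng.standard_normal(16000), rate_hz=16000.0)
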