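import numpy as np
import pytest

from damo.motif_models import BASES, PFM, PWM


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_pwm(rng, width, scale=1.0, name="rand"):
    return PWM(rng.normal(0.0, scale, size=(4, width)), name=name)


def random_pfm(rng, width, concentration=0.5, name="rand_pfm"):
    return PFM(rng.dirichlet(np.full(4, concentration), size=width).T, name=name)


def random_seq(rng, length, alphabet=BASES):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
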