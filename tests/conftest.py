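import numpy as np
import pytest

from hairpinscan.thermo import load_default_params


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_arm(rng, length, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=length))


def random_wc_complement(rng, length):
    """A perfect Watson-Crick stem-arm pair (no wobble pairs)."""
    st1 = random_arm(rng, length)
    wc = {"A": "U", "U": "A", "G": "C", "C": "G"}
    st2 = "".join(wc[b] for b in st1)  # already 3'->5' column-wise
    return st1, st2
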