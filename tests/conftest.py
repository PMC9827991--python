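import numpy as np
import pytest

from telospect import build_reference


@pytest.fixture(scope="session")
def ref():
    return build_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20221011)


def random_read(rng, length=150):
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng, seq, rate):
    bases = "ACGT"
    out = []
    for b in seq:
        if rng.random() < rate:
            out.append(bases[int(rng.integers(0, 4))])
        else:
            out.append(b)
    return "".join(out)
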