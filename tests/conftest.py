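import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20150812)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng, seq: str, n_subs: int) -> str:
    """Introduce exactly n_subs substitutions at distinct positions."""
    s = list(seq)
    pos = rng.choice(len(s), size=n_subs, replace=False)
    for p in pos:
        s[p] = "ACGT"[(("ACGT".index(s[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(s)
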