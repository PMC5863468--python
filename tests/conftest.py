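import numpy as np
import pytest

from fshash import parse_seed


def random_pattern(rng, max_span=16, max_weight=12):
    """Random valid seed pattern: starts and ends with '1', weight capped."""
    span = int(rng.integers(1, max_span + 1))
    if span == 1:
        return "1"
    while True:
        mid = rng.integers(0, 2, size=span - 2)
        pat = "1" + "".join(map(str, mid)) + "1"
        if pat.count("1") <= max_weight:
            return pat


def random_dna(rng, length, n_prob=0.0):
    """Random sequence over ACGT with optional per-base chance of N."""
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=length)]
    if n_prob > 0 and length > 0:
        seq[rng.random(length) < n_prob] = "N"
    return "".join(seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def example_seed():
    """The worked-example seed: shape {0,2,3,4,6,7}, weight 6, span 8."""
    return parse_seed("10111011")
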