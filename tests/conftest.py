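import numpy as np
import pytest


def naive_partition_score(y, labels):
    """Independent brute-force evaluation of the partition score.

    Deliberately written as a plain double loop over levels and
    subjects, sharing no code with the package implementation.
    """
    y = list(map(float, y))
    n = len(y)
    ybar = sum(y) / n
    s2 = sum((v - ybar) ** 2 for v in y) / (n - 1)
    total = 0.0
    for level in set(labels):
        members = [y[i] for i in range(n) if labels[i] == level]
        ni = len(members)
        if ni == 0:
            continue
        yi = sum(members) / ni
        total += (ni / n) * (yi - ybar) ** 2 / (s2 / ni)
    return total


@pytest.fixture
def naive_score():
    return naive_partition_score


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
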