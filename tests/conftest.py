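import math

import numpy as np
import pytest

from spatiodyn import (
    SyntheticConfig,
    generate_dataset,
    make_parcellation,
    make_template,
)


@pytest.fixture(scope="session")
def parc246():
    """Default 246-ROI parcellation over the eight base networks."""
    return make_parcellation(246)


@pytest.fixture(scope="session")
def tiny_parc():
    """Minimal parcellation: one ROI per network plus one extra subcortical."""
    sizes = {"SCN": 2, "LIM": 1, "SMN": 1, "VIS": 1, "VAN": 1,
             "DAN": 1, "FPN": 1, "DMN": 1}
    return make_parcellation(9, sizes)


@pytest.fixture(scope="session")
def traveling_template(parc246):
    return make_template(parc246, 32, "traveling", math.pi / 2)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Planted traveling pattern at the default study conditions, no noise."""
    return generate_dataset(SyntheticConfig(snr=float("inf")), 7)


@pytest.fixture(scope="session")
def snr1_dataset():
    """Default study conditions (SNR 1, AR(1) noise), seed 1."""
    return generate_dataset(SyntheticConfig(), 1)


def brute_force_max_matching(a, b, cushion):
    """Exhaustive maximum one-to-one matching size under |ta − tb| <= cushion.

    Independent oracle for the greedy sweep: recursion over injective
    pairings, exponential, only for tiny sets.
    """
    a = list(a)
    b = list(b)

    def rec(i, used):
        if i == len(a):
            return 0
        best = rec(i + 1, used)   # leave a[i] unmatched
        for j, tb in enumerate(b):
            if j not in used and abs(a[i] - tb) <= cushion:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


def circular_correlation(a, b):
    """Fisher–Lee circular correlation between two angle vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    am = np.angle(np.mean(np.exp(1j * a)))
    bm = np.angle(np.mean(np.exp(1j * b)))
    num = np.sum(np.sin(a - am) * np.sin(b - bm))
    den = np.sqrt(np.sum(np.sin(a - am) ** 2) * np.sum(np.sin(b - bm) ** 2))
    return num / den
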