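"""Shared fixtures: fixture models and a cached pool of random instances."""

import warnings

import numpy as np
import pytest

from egmodes import (RandomModelSpec, random_model_with_probe,
                     two_enzyme_model, toxin_model)

# (m, n) sizes cycled over by the random-instance pool
_SIZES = [(2, 3), (3, 4), (2, 4), (3, 5), (4, 5), (4, 6), (3, 6), (2, 2)]


def make_instances(count, seed_offset=0):
    """Generate `count` random models with certified (x, mu) probes."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # byproduct notices
        for i in range(count):
            m, n = _SIZES[i % len(_SIZES)]
            spec = RandomModelSpec(m=m, n=n, seed=seed_offset + i)
            out.append(random_model_with_probe(spec))
    return out


@pytest.fixture(scope="session")
def random_instances():
    """20 seeded random whole-cell models with feasible probe points."""
    return make_instances(20)


@pytest.fixture()
def fig_two_enzyme():
    return two_enzyme_model()


@pytest.fixture()
def fig_toxin_free():
    return toxin_model(toxin_outside=0.0)


@pytest.fixture()
def probe_x():
    return np.array([0.2])
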