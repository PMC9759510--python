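"""Shared fixtures: the expensive analysis chains are built once per session.

The reference wave branch (Hopf entry at c = 0.1 continued down to
c = 1e-4) and the outer solution bootstrapped from it back most of the
suite, including the acceptance tests.
"""

import numpy as np
import pytest

from drylandwaves.layers import matching_constants
from drylandwaves.model import Params
from drylandwaves.pipeline import outer_reference, profile_at_c, speed_branch


@pytest.fixture(scope="session")
def fig2_params() -> Params:
    return Params(a=0.727, b=0.45, nu=18.25, d=0.5625, eta=0.75)


@pytest.fixture(scope="session")
def branch(fig2_params):
    """Reference c-branch at the study parameters, with intermediates."""
    br = speed_branch((0.1, 0.01, 0.001, 0.0001), fig2_params,
                      keep_intermediate=True)
    assert br.complete
    return br


@pytest.fixture(scope="session")
def wave_c01(branch):
    return profile_at_c(branch, 0.1)


@pytest.fixture(scope="session")
def wave_c1e3(branch):
    return profile_at_c(branch, 1e-3)


@pytest.fixture(scope="session")
def outer_ref(wave_c1e3):
    """Outer solution bootstrapped by stripping the c = 1e-3 spike."""
    return outer_reference(wave_c1e3)


@pytest.fixture(scope="session")
def constants(outer_ref):
    return matching_constants(outer_ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
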