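"""Shared fixtures.

The expensive best-fit simulations (D = 5000 nm^2/s, LS = 12, S_load = 1.7 Hz)
are session-scoped so the plateau, decay and invariant checks share traces.
All seeds are fixed for reproducibility.
"""

import numpy as np
import pytest

import flagrow as fg

BEST_D = 5000.0
BEST_LS = 12


@pytest.fixture(scope="session")
def decay_trace():
    """One best-fit trace into the diffusion-limited regime (to 4200 nm)."""
    return fg.simulate(fg.SimParams(D=BEST_D, LS=BEST_LS, L_stop=4200.0, seed=7))


@pytest.fixture(scope="session")
def plateau_traces(decay_trace):
    """Three replicate best-fit traces covering the plateau (to >= 1600 nm).

    The long decay trace doubles as one replicate; its 400-1500 nm stretch is
    statistically identical to a dedicated short trace.
    """
    return [decay_trace] + [
        fg.simulate(fg.SimParams(D=BEST_D, LS=BEST_LS, L_stop=1600.0, seed=s))
        for s in (1, 2)
    ]


@pytest.fixture()
def fast_params():
    """Cheap loading-limited parameters for second-scale simulator tests."""
    return fg.SimParams(D=2.0e4, LS=25, L_stop=400.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
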