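import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from morphoinfer import (
    CellEnsembleState,
    PrecisionConfig,
    build_target,
    default_target,
    sense,
)
from morphoinfer.model_core import CELL_TYPES


@pytest.fixture(scope="session")
def morph():
    """The packaged eight-slot planarian-like axis."""
    return default_target()


@pytest.fixture(scope="session")
def tiny_morph():
    """Three slots, four channels — cheap fixture for gradient oracles."""
    return build_target(
        {
            "slot_types": ["head", "intestine", "tail"],
            "ex_star": [[0.0, 0.0, 0.0], [1.5, 0.0, -1.5]],
            "expression_amplitude": 2.0,
            "tau": 1.0,
            "k": 0.8,
        }
    )


@pytest.fixture(scope="session")
def single_slot_morph():
    """One cell, one slot: the exact fixed point of the model."""
    return build_target(
        {
            "slot_types": ["intestine"],
            "ex_star": [[0.0], [0.0]],
            "expression_amplitude": 1.0,
            "tau": 1.0,
            "k": 1.0,
        }
    )


def random_ensemble(morph, rng, n_orders=3, spread=1.0):
    """A random sensed ensemble state matched to ``morph``."""
    n, S, C = morph.n_slots, morph.n_slots, morph.n_channels
    internal = np.zeros((n, n_orders, S))
    internal[:, 0, :] = spread * rng.standard_normal((n, S))
    active = np.zeros((n, n_orders, 2 + C))
    active[:, 0, :2] = spread * rng.standard_normal((n, 2))
    active[:, 0, 2:] = np.abs(spread * rng.standard_normal((n, C)))
    ens = CellEnsembleState(
        internal=internal,
        active=active,
        sc=np.zeros((n, C)),
        sx=np.zeros((n, 2)),
        s_lambda=np.zeros((n, C)),
    )
    return sense(ens, morph)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
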