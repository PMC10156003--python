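import numpy as np
import pytest

from abmcal.abm import KINDS, SimConfig, SimulationState


def make_state(positions, kinds, pdl1=None, radius=10.0, origin=None) -> SimulationState:
    """Hand-built simulation state for unit tests."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    codes = np.array([KINDS.index(k) for k in kinds], dtype=np.int8)
    return SimulationState(
        ids=np.arange(n, dtype=np.int64),
        kind=codes,
        pos=pos,
        radius=np.full(n, radius),
        pdl1=np.zeros(n) if pdl1 is None else np.asarray(pdl1, dtype=float),
        t=0,
        next_id=n,
        origin=np.asarray(origin, dtype=float) if origin is not None else pos.mean(axis=0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    """Small, quick simulation configuration for unit tests."""
    return SimConfig(n_steps=25, initial_tumor_radius=60.0, recruitment_rate=1.5)
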