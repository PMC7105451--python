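import numpy as np
import pytest
from hypothesis import settings

from tislet import MechanicsParams, SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def params():
    """Published mechanics constants (Table-1 values)."""
    return MechanicsParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_config(**kw):
    """A fast, deterministic config for kernel-level unit tests."""
    base = dict(seed=0, scenario="none", t_end=0.01, dt=0.01, eta=0.0,
                n_tcells=0, mutation_trigger_rate=0.0, mutation_rate=0.0,
                division_rate=0.0, death_rate=0.0, signal_threshold=0.0,
                snapshot_every=0.01, max_cells=64)
    base.update(kw)
    return SimulationConfig(**base)
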