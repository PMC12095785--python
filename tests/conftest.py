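import numpy as np
import pytest

from plastmap import synthgen


@pytest.fixture(scope="session")
def small_cfg() -> synthgen.SynthConfig:
    """Reduced cohort used across module tests (fast, 7 networks intact)."""
    return synthgen.SynthConfig(
        n_subjects=8, n_nodes=42, n_genes=120, n_timepoints=100,
        planted_genes=tuple(range(12)), planted_effect_size=1.0,
        dispersion_behavior_coupling=0.8, seed=7)


@pytest.fixture(scope="session")
def small_geom(small_cfg):
    return synthgen.gen_geometry(small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
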