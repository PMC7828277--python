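import numpy as np
import pytest

from cuffdrift import orchestration as orch
from cuffdrift.cap_simulator import SourceTemplate, default_pathway
from cuffdrift.volume_conductor import CuffGeometry, TissueModel


@pytest.fixture(scope="session")
def geometry():
    return CuffGeometry()


@pytest.fixture(scope="session")
def tissue():
    return TissueModel()


@pytest.fixture(scope="session")
def template():
    return SourceTemplate()


@pytest.fixture(scope="session")
def tibial_pathway(tissue):
    return default_pathway("tibial", tissue, n_offsets=4, seed=3)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config small enough for per-module tests."""
    return orch.RunConfig(
        n_per_class=60,
        n_offsets=4,
        scenarios=("encapsulation",),
        snr_grid=(-5.0,),
        min_per_class=5,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_inputs(small_config):
    return orch.build_study_inputs(small_config)


@pytest.fixture(scope="session")
def small_encap_seq(small_config, small_inputs):
    """Encapsulation sequence, 180 signatures per time point at -5 dB."""
    return orch.build_sequence(small_config, small_inputs, "encapsulation", -5.0)


@pytest.fixture(scope="session")
def toy_separable():
    """Linearly separable toy signatures: one class-specific channel block."""
    rng = np.random.default_rng(0)
    n = 60
    X = rng.normal(0, 0.05, (3 * n, 56, 100))
    y = np.repeat(np.arange(3), n)
    for c in range(3):
        X[y == c, 10 + 10 * c : 15 + 10 * c, 40:60] += 0.8
    return X, y
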