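import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from relq.simulate import SimConfig, generate_experiment, to_experiment


@pytest.fixture(scope="session")
def sp_sim():
    """A compact single-plate two-condition study: C vs S1, 7 GOIs + refG,
    4-fold induction, 0.05-cycle replicate noise."""
    cfg = SimConfig(replicate_noise_sd=0.05, seed=11)
    plates, truth = generate_experiment(cfg)
    return cfg, plates, truth


@pytest.fixture
def sp_experiment(sp_sim):
    return to_experiment(sp_sim[1])


@pytest.fixture(scope="session")
def mp_sim():
    """Three samples over two plates with a +0.5-cycle offset on plate 2,
    an IPC sample on both plates, and reference wells kept on plate 1 so
    cross-plate contrasts exist."""
    cfg = SimConfig(
        n_samples=3,
        n_plates=2,
        plate_offsets=(0.0, 0.5),
        ipc_enabled=True,
        split_reference_plate=True,
        replicate_noise_sd=0.05,
        seed=23,
    )
    plates, truth = generate_experiment(cfg)
    return cfg, plates, truth


@pytest.fixture
def mp_experiment(mp_sim):
    return to_experiment(mp_sim[1])
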