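import numpy as np
import pytest

from mpfm.core_io import BOLDDataset, BOLDRun
from mpfm.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_run(rng):
    return BOLDRun(data=rng.normal(size=(100, 50)), tr=0.72,
                   subject_id="subA", run_id="run1")


@pytest.fixture()
def tiny_dataset(rng):
    runs = [
        BOLDRun(data=rng.normal(size=(60, 40)), tr=1.0,
                subject_id=f"s{i}", run_id=f"run{r}")
        for i in range(3) for r in (1, 2)
    ]
    return BOLDDataset(runs=runs)


@pytest.fixture(scope="session")
def micro_sim():
    """A small but structured simulated dataset shared across tests."""
    cfg = SimulationConfig(n_subjects=8, n_runs=2, n_voxels=800,
                           n_timepoints=120, n_datasets=1, seed=42)
    dataset, truth = simulate_dataset(cfg, 4242)
    return cfg, dataset, truth
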