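import numpy as np
import pytest

from leafsen.normalize import build_experiment
from leafsen.pipeline import run_pipeline
from leafsen.simulate import (
    SimulationConfig,
    generate_experiment,
    study_archetype_counts,
)


@pytest.fixture(scope="session")
def small_study():
    """400-gene study draw shared by the slower integration tests."""
    cfg = SimulationConfig(n_genes=study_archetype_counts(400), seed=11)
    cm, truth = generate_experiment(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def small_experiment(small_study):
    _, cm, _ = small_study
    return build_experiment(cm)


@pytest.fixture(scope="session")
def small_results(small_study):
    _, cm, _ = small_study
    return run_pipeline(cm, {"seed": 11})


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero-dispersion absolute-mean draw: planted profiles held exactly."""
    cfg = SimulationConfig(
        n_genes=study_archetype_counts(200), seed=5, nb_dispersion=0.0,
        scale_to_library=False, library_imbalance=0.0, baseline_log2_sd=0.5,
    )
    cm, truth = generate_experiment(cfg)
    return cfg, cm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
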