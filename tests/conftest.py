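import numpy as np
import pytest

from napamyloid.simulate import (
    AxonPopulationModel,
    DrugEffectModel,
    ExperimentDesign,
    StimulusProtocol,
)


@pytest.fixture(scope="session")
def protocol() -> StimulusProtocol:
    return StimulusProtocol()


@pytest.fixture(scope="session")
def population() -> AxonPopulationModel:
    return AxonPopulationModel()


@pytest.fixture(scope="session")
def quiet_population() -> AxonPopulationModel:
    """Fully deterministic waveforms: no additive noise, no drift."""
    return AxonPopulationModel(noise_sd=0.0, gain_jitter=0.0, latency_jitter=0.0)


@pytest.fixture(scope="session")
def drug() -> DrugEffectModel:
    return DrugEffectModel()


@pytest.fixture(scope="session")
def null_drug() -> DrugEffectModel:
    return DrugEffectModel(effect_by_conc={c: 0.0 for c in range(9)})


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    """12 nerves over 5 groups, 6 segments: fast end-to-end runs."""
    return ExperimentDesign(
        conc_groups={
            0: (0.0, 4),
            1: (70e-12, 2),
            2: (700e-12, 2),
            3: (7e-9, 2),
            4: (70e-9, 2),
        },
        n_segments=6,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
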