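import pytest

from phagedrop.simulate import SimulationConfig


@pytest.fixture
def reference_config() -> SimulationConfig:
    """The assay's reference condition: λ_phg=0.2, ~19 cells/droplet,
    40k events per timepoint, artifacts active only from 7 h."""
    return SimulationConfig(seed=2024)


@pytest.fixture
def small_config() -> SimulationConfig:
    """Scaled-down single-timepoint condition for fast integration tests."""
    return SimulationConfig(
        seed=7,
        n_droplets=20_000,
        timepoints_h=(0.0, 5.0),
        artifact_prob=0.0,
    )
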