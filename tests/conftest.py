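import pytest
from hypothesis import settings

from clusterbind.experiments import ExperimentConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_cfg() -> ExperimentConfig:
    """Miniature system for fast pipeline plumbing tests (not physics)."""
    return ExperimentConfig(
        area_ratio=100.0,
        r0=10,
        n_steps=400,
        burn_in=200,
        window=200,
        replicates=2,
        slope_replicates=2,
        fpt_particles=300,
        fpt_max_steps=400,
        seed=123,
    )
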