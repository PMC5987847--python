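import numpy as np
import pytest

from edumr import ScenarioConfig, analysis_frame, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20180606)


@pytest.fixture(scope="session")
def forward_cohort():
    """Medium forward-causal cohort shared across tests (true effect
    -0.27 D/y, default confounding, no pleiotropy)."""
    cfg = ScenarioConfig(n_participants=6000, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def forward_frame(forward_cohort):
    return analysis_frame(forward_cohort)


def small_config(**kw) -> ScenarioConfig:
    """Cheap scenario for replicate simulations: few variants, stronger
    education score so the instrument is not weak at small n."""
    defaults = dict(
        n_participants=1500,
        n_edu_variants=8,
        n_myo_variants=6,
        variance_explained_edu_score=0.03,
        age_effect_edu=0.0,
        age_effect_mse=0.0,
        n_repeats=1,
        eye_condition_rate=0.0,
        born_outside_rate=0.0,
        missing_education_rate=0.0,
        unreliable_rate=0.0,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)
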