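import numpy as np
import pytest

from emgait import PopulationConfig, generate_population


@pytest.fixture(scope="session")
def small_population():
    """2 horses × 2 sessions under default variability (seed fixed)."""
    return generate_population(PopulationConfig(n_horses=2, n_sessions=2, seed=7))


@pytest.fixture(scope="session")
def clean_session():
    """One recording with every variability source disabled: the raw sEMG is
    the noiseless template times the carrier, truth is exact."""
    cfg = PopulationConfig(
        n_horses=1,
        n_sessions=1,
        inter_horse_sd=0.0,
        intra_horse_sd=0.0,
        session_effect_sd=0.0,
        noise_floor=0.0,
        marker_noise_sd=0.0,
        outlier_rate=0.0,
        stride_duration_sd=0.0,
        velocity_sd=0.0,
        seed=11,
    )
    return generate_population(cfg)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
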