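import numpy as np
import pytest
from hypothesis import settings

from ppgdx.preprocess import gain_normalize
from ppgdx.recording import ProtocolConfig
from ppgdx.synthetic import PhenotypeDistributions, generate_cohort

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolConfig:
    """Desk-scale protocol: same 3-phase structure, 2 minutes at 200 Hz."""
    return ProtocolConfig(fs=200.0, duration=120.0, baseline_end=60.0, occlusion_end=90.0)


@pytest.fixture(scope="session")
def small_cohort(short_protocol):
    """4 SSc + 6 Control recordings with strongly separated phenotypes."""
    recordings, manifest = generate_cohort(
        4, 6, short_protocol, PhenotypeDistributions.strongly_separated(), seed=11
    )
    return recordings, manifest


@pytest.fixture(scope="session")
def small_cohort_normalised(small_cohort):
    recordings, manifest = small_cohort
    return [gain_normalize(r) for r in recordings], manifest


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
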