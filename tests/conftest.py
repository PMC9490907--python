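import numpy as np
import pytest
from hypothesis import settings

from lfbmil.config import SimConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from lfbmil.labels import DonorRecord
from lfbmil.simulate import generate_slide


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Compact generator settings used by image-level tests."""
    return SimConfig(n_donors=8, slide_px=512, effect_size=0.3,
                     patchiness=1.0, stain_gain_sd=0.05, seed=11)


def make_donor(i: int, state: str) -> DonorRecord:
    return DonorRecord(donor_id=f"D{i:04d}", age=85.0, sex="F", true_state=state)


@pytest.fixture(scope="session")
def example_slide(small_sim_config):
    return generate_slide(make_donor(0, "NCI"), small_sim_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
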