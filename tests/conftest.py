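import numpy as np
import pytest

from mpcad.config import PipelineConfig
from mpcad.phantom import Lesion, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_case():
    """One noiseless phantom with a single lesion and one mimic."""
    spec = PhantomSpec(
        tumours=[Lesion(center=(17.0, 22.0, 3.5), radius_vox=(3.5, 3.2, 1.6))],
        mimics=[Lesion(center=(24.0, 14.0, 3.5), radius_vox=(2.8, 2.6, 1.4),
                       d_lesion=0.85e-3, t2w_contrast=1.05)],
        noise_sigma=0.0,
        s0_variation=0.0,
        seed=7,
        patient_id="clean",
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
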