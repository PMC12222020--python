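import numpy as np
import pytest

from fnmes_eeg.design import build_trial_design, subsample_design
from fnmes_eeg.simulate import EffectParams, NoiseSpec, simulate_epochs


@pytest.fixture(scope="session")
def design_two_subjects():
    return build_trial_design(2, seed=7)


@pytest.fixture(scope="session")
def face_design(design_two_subjects):
    """Reduced face-trial design: 3 trials per subject x emotion x fnmes."""
    return subsample_design(design_two_subjects, 3, seed=1, face_only=True)


@pytest.fixture(scope="session")
def quiet_epochs(face_design):
    """Noise-free, beta-free epochs in float64: planted N170 only."""
    params = EffectParams(beta_amp_uv=0.0)
    epochs, truth = simulate_epochs(
        face_design, params, NoiseSpec(pink_rms_uv=0.0, white_sd_uv=0.0),
        seed=11, dtype=np.float64)
    return epochs, truth, params


@pytest.fixture(scope="session")
def noisy_epochs(face_design):
    params = EffectParams()
    epochs, truth = simulate_epochs(face_design, params, NoiseSpec(),
                                    seed=13)
    return epochs, truth, params
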