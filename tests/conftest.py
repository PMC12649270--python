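import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bvrkin.scene import TrialConfig, build_geometry, generate_specimen


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def specimen():
    return generate_specimen(seed=11, specimen_id=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation_matrices(seed, n):
    from scipy.spatial.transform import Rotation

    return Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()


@pytest.fixture(scope="session")
def quiet_trial_cfg():
    """Noise-free hop trial configuration (null pipeline conditions)."""
    return TrialConfig(
        motion="hop",
        mean_speed_mps=0.9,
        speed_sd_mps=0.0,
        duration_s=0.3,
        seed=7,
        bead_pixel_noise_sd=0.0,
        model_rot_noise_sd=0.0,
        model_trans_noise_sd=0.0,
        outlier_frame_prob=0.0,
    )
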