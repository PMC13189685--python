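import numpy as np
import pytest

from graspdce import phantom as P
from graspdce import radial


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_lesion_phantom():
    """32x32 phantom with one lesion, one muscle region and an aorta."""
    regions = [
        P.Region("lesion_0", (20.0, 20.0), 4.0, 0.33, 0.25, 1.0),
        P.Region("muscle", (29.0, 3.0), 2.0, 0.02, 0.10, 1.0),
    ]
    aorta = P.Region("aorta", (4.0, 4.0), 2.5, 0.0, 1.0, 1.0)
    spec = P.PhantomSpec(
        grid_size=32,
        region_defs=regions,
        aorta_region=aorta,
        n_timepoints=16,
        frame_interval=10.0,
        noise_sd=0.0,
        n_coils=4,
        seed=11,
    )
    return P.generate_phantom(spec)


@pytest.fixture(scope="session")
def nyquist_trajectory_32():
    """Fully sampled (2x angular Nyquist) trajectory for a 32 grid."""
    spokes = int(np.ceil(np.pi / 2 * 32) * 2)
    return radial.golden_angle_trajectory(spokes, 64, tr_seconds=0.01)
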