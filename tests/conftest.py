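import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from chromagrain import ChannelRole, ChannelSim, SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20230515)


def small_scene_params(seed: int = 0, granule_count=12, noise_sd: float = 20.0,
                       amplitude: float = 1800.0, n_nuclei: int = 1) -> SceneParams:
    """Desk-scale single-nucleus scene used across tests: 256x256 frame,
    two-mode label channel (diffuse 800, granules 2600)."""
    return SceneParams(
        frame_size=(256, 256),
        n_nuclei=n_nuclei,
        nucleus_axes_px=(50.0, 70.0),
        channels={
            ChannelRole.COHESIN: ChannelSim(
                granule_count=granule_count,
                granule_radius_px=(2.0, 3.5),
                granule_amplitude=amplitude,
                noise_sd=noise_sd,
            )
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def highsnr_scene():
    """One 256x256 high-SNR scene with 12 planted cohesin granules."""
    return generate_scene(
        SceneParams(
            frame_size=(256, 256),
            n_nuclei=1,
            nucleus_axes_px=(50.0, 70.0),
            channels={
                ChannelRole.COHESIN: ChannelSim(
                    granule_count=12, granule_radius_px=(2.0, 3.5)
                )
            },
            seed=7,
        )
    )
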