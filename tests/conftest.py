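import numpy as np
import pytest

from stainscan import default_protocol, default_scene, render_pair
from stainscan.cube import ChannelMeta, ImageStack


@pytest.fixture(scope="session")
def protocol48():
    """Full 48-channel grid at desk-scale frames (96 x 128 px)."""
    return default_protocol(frame_height=96, frame_width=128)


@pytest.fixture(scope="session")
def noise_free_pair(protocol48):
    """Noise-free reference phantom: 3 x 1.5 mm stain -> 60 x 30 px at
    (row 30, col 30), rendered under the full protocol."""
    scene = default_scene(seed=0, noise_sd=0.0)
    dirty, clean, truth = render_pair(scene, protocol48)
    return scene, dirty, clean, truth


def make_stack(frames, lights=None, filters=None, i_rel=255):
    """Small hand-built stack for unit tests; frames is (C, H, W)-like."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[0]
    lights = lights or ["green"] * n
    filters = filters or [420.0 + 20.0 * i for i in range(n)]
    meta = [
        ChannelMeta(light=lights[i], center_nm=525.0, i_rel=i_rel, filter_nm=filters[i])
        for i in range(n)
    ]
    return ImageStack(frames=frames, channel_meta=meta)
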