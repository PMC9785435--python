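import numpy as np
import pytest

from irislocate.config import PipelineConfig
from irislocate.geometry import Circle
from irislocate.synthgen import SceneSpec, render_scene


@pytest.fixture
def cfg():
    return PipelineConfig()


def make_disk(radius=20.0, inside=0.1, outside=0.9, size=101, center=None):
    """Hard-edge disk image: ``inside`` where rho <= radius, else ``outside``."""
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    cy, cx = center[1], center[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rho = np.hypot(xx - cx, yy - cy)
    return np.where(rho <= radius, inside, outside), Circle(cx, cy, radius)


@pytest.fixture
def hard_disk():
    return make_disk()


@pytest.fixture
def clean_scene():
    spec = SceneSpec(blur_sigma=0.5, seed=42)
    return render_scene(spec)


@pytest.fixture
def noiseless_spec():
    return SceneSpec(
        iris_texture_amplitude=0.0,
        blur_sigma=0.0,
        seed=5,
    )
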