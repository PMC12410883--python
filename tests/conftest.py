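import numpy as np
import pytest

from axonmetrics.morphometry import measure_instances
from axonmetrics.phantom import PopulationConfig, generate_phantom
from axonmetrics.segmentation import segment

PX_UM = 0.01728  # default pixel size in µm


@pytest.fixture(scope="session")
def phantom_50():
    """Undegraded, non-kissing 50-fiber phantom with its ground truth."""
    cfg = PopulationConfig(fiber_count=50, canvas_px=(1400, 1400), seed=7)
    smap, inst, truth = generate_phantom(cfg)
    return cfg, smap, inst, truth


@pytest.fixture(scope="session")
def segmented_50(phantom_50):
    cfg, smap, inst, truth = phantom_50
    return segment(smap)


@pytest.fixture(scope="session")
def measured_50(segmented_50):
    return measure_instances(segmented_50)


@pytest.fixture(scope="session")
def phantom_degenerate_g():
    """Phantom whose g-ratio law is a point mass at 0.54."""
    cfg = PopulationConfig(
        fiber_count=40, canvas_px=(1300, 1300), seed=3, g_ratio_sd=0.0
    )
    smap, inst, truth = generate_phantom(cfg)
    return cfg, smap, inst, truth


def disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
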