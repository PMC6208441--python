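import numpy as np
import pytest

from gramirice.brdf import KernelParams
from gramirice.synth import SceneConfig, geostationary_schedule, synth_landscape, synth_weather


@pytest.fixture(scope="session")
def true_kernel_params():
    return {
        "red": KernelParams(0.20, 0.02, 0.10, "red"),
        "nir": KernelParams(0.40, 0.03, 0.20, "nir"),
    }


@pytest.fixture(scope="session")
def window_schedule():
    """One 16-day geostationary acquisition window (dense diurnal sampling)."""
    return geostationary_schedule(doys=np.arange(180, 196))


@pytest.fixture(scope="session")
def weather_year():
    return synth_weather(seed=3)


@pytest.fixture(scope="session")
def default_scene():
    """The default 50x50 synthetic landscape (seed 7)."""
    return synth_landscape(SceneConfig())


@pytest.fixture(scope="session")
def scene_feature_matrix(default_scene):
    from gramirice.pipeline import scene_features

    return scene_features(default_scene)
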