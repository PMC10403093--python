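import numpy as np
import pandas as pd
import pytest

from porpclick.simulate import ArrayGeometry, SceneConfig, render_scene


@pytest.fixture(scope="session")
def default_geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def small_scene():
    """A small deterministic scene used by several stage tests."""
    cfg = SceneConfig(seed=42, n_trains=6, range_span=(5.0, 25.0))
    return render_scene(cfg)


@pytest.fixture(scope="session")
def event_frame():
    """Hand-built single-sensor pulse-event stream helper."""

    def make(times, pp=None, sensor="atag_4m"):
        times = np.asarray(times, dtype=float)
        pp = np.asarray(pp, dtype=float) if pp is not None else np.full(len(times), 10.0)
        return pd.DataFrame(
            {
                "time": times,
                "pp_ch1": pp,
                "pp_ch2": pp * 0.75,
                "tdoa": np.zeros(len(times)),
                "sensor_id": sensor,
            }
        )

    return make


def run_state(scene):
    """Initial pipeline state dict for a rendered scene."""
    return {
        "events": scene.events,
        "scene": scene,
        "sound_speed": scene.sound_speed,
        "alpha": scene.alpha_db_per_m,
        "water": scene.config.water,
    }
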