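import numpy as np
import pytest

import loopscope as ls


@pytest.fixture
def tiny_plan():
    """Two positions: one closed-loop bang-bang, one open-loop bars."""
    sched = ls.ScheduleConfig(
        experiment_length_s=240.0, imaging_interval_s=120.0, stimulation_interval_s=60.0, seed=7
    )
    positions = [ls.StagePosition("A1", 0.0, 0.0), ls.StagePosition("B1", 900.0, 0.0)]
    cfg_a = ls.PositionConfig(
        position_name="A1",
        pattern={"module": "bangbang", "setpoint": 200.0, "channel": "fluor"},
        segmentation={"module": "threshold", "channel": "nuclear", "smooth_sigma": 2.0, "min_area": 9},
        channels=[{"name": "nuclear", "exposure_ms": 50.0}, {"name": "fluor", "exposure_ms": 50.0}],
        pixel_size_um=1.0,
        fov_shape=(160, 160),
        simulate={"n_cells": 25},
    )
    cfg_b = ls.PositionConfig(
        position_name="B1",
        pattern={"module": "bars", "period_um": 80.0, "speed_um_per_h": 12.0, "duty": 0.5},
        segmentation=None,
        channels=[{"name": "nuclear", "exposure_ms": 50.0}],
        pixel_size_um=1.0,
        fov_shape=(160, 160),
        simulate={"n_cells": 25},
    )
    return ls.build_experiment_plan(sched, positions, [cfg_a, cfg_b])


@pytest.fixture
def rendered_fixture():
    """A rendered nuclear/fluor frame pair with ground truth, well separated."""
    rng = np.random.default_rng(42)
    cam = ls.CameraModel(pixel_size_um=1.0, fov_shape=(256, 256))
    pop = ls.init_population(50, cam.fov_um, heterogeneity_cv=0.45, seed=rng, arrangement="grid")
    nuclear = ls.render_image(pop, "nuclear", cam, rng)
    fluor = ls.render_image(pop, "fluor", cam, rng)
    return {"pop": pop, "cam": cam, "nuclear": nuclear, "fluor": fluor}
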