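import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fruittrack as ft

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_scene():
    """50 well-separated fruit, 80 frames, no detector errors."""
    cfg = ft.SceneConfig(n_frames=80, n_fruit=50, min_separation=60.0, seed=3)
    scene = ft.generate_scene(cfg)
    frames, truth = ft.render_detections(scene)
    return cfg, scene, frames, truth


@pytest.fixture(scope="session")
def field_scene():
    """Field-condition scene: ~30 visible fruit/frame, ~1.4 FP and ~1.4 FN
    per frame, occlusions, small rotation/position jitter."""
    cfg = ft.SceneConfig(
        n_frames=120,
        n_fruit=100,
        fn_prob=1.4 / 31,
        fp_rate=1.4,
        position_noise_sd=2.0,
        rotation_jitter_sd=0.15,
        occlusion_rate=0.01,
        mean_occlusion_len=5.0,
        seed=11,
    )
    frames, truth, scene = ft.simulate(cfg)
    return cfg, scene, frames, truth


def constant_velocity_stream(n_frames=30, x0=100.0, y0=485.0, v=(20.0, 0.0),
                             absent=(), box=(30.0, 30.0)):
    """Hand-built single-fruit detection stream moving at constant velocity."""
    frames = {}
    for k in range(n_frames):
        if k in absent:
            frames[k] = []
        else:
            cx, cy = x0 + v[0] * k, y0 + v[1] * k
            frames[k] = [
                ft.Detection(k, cx - box[0] / 2, cy - box[1] / 2, box[0], box[1])
            ]
    return frames


def brute_force_lap_cost(C):
    """Minimum total assignment cost by exhaustive permutation enumeration."""
    import itertools

    C = np.asarray(C, dtype=float)
    m, n = C.shape
    if m == 0 or n == 0:
        return 0.0
    if m <= n:
        return min(
            sum(C[i, p[i]] for i in range(m))
            for p in itertools.permutations(range(n), m)
        )
    return brute_force_lap_cost(C.T)
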