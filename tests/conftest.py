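"""Shared fixtures: small synthetic scenes used across test modules."""

import numpy as np
import pytest

from valveflow import videogen as vg
from valveflow.io import ROISpec


@pytest.fixture(scope="session")
def short_heart_scene():
    """5 s dye-angiography scene, moderate noise, wildtype valve."""
    params = vg.SceneParams(duration=5.0, noise_sd=3.0, seed=42)
    stack, truth = vg.generate_heart_video(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def clean_heart_scene():
    """Noise-free short scene for exact oracles."""
    params = vg.SceneParams(duration=2.0, noise_sd=0.0,
                            background_drift_per_s=0.0, seed=0)
    stack, truth = vg.generate_heart_video(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def valve_label_scene():
    """5 s semi-intact valve-label recording at 200 fps."""
    params = vg.SceneParams(duration=5.0, frame_rate=200.0, beat_rate=2.0,
                            noise_sd=3.0, image_size=(48, 128),
                            valve_position_col=64, seed=4)
    stack, truth = vg.generate_valve_label_video(params)
    return params, stack, truth


def wide_tube_params(**kw):
    """Particle-scene geometry wide enough for many non-crossing lanes."""
    defaults = dict(
        duration=1.5, frame_rate=200.0, image_size=(160, 256), pixel_size=2.5,
        tube_axis_row=80, tube_width=350.0, valve_position_col=128,
        packet_velocity=0.5, noise_sd=2.0, seed=5,
    )
    defaults.update(kw)
    return vg.SceneParams(**defaults)


@pytest.fixture(scope="session")
def particle_scene():
    params = wide_tube_params()
    stack, truth = vg.generate_particle_video(params, 10)
    return params, stack, truth


def anterior_roi(params, size=15):
    """15x15 ROI at the anterior accumulation zone."""
    return ROISpec("anterior", params.tube_axis_row - size // 2,
                   params.image_size[1] - size - 1, size, size)


def perivalve_roi(params, offset=20, size=15):
    """15x15 ROI just anterior to the valve."""
    return ROISpec("perivalve", params.tube_axis_row - size // 2,
                   params.valve_position_col + offset, size, size)
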