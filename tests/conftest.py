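import dataclasses

import numpy as np
import pytest

from plantarkit import mosaic, phantom


@pytest.fixture(scope="session")
def platform_scene():
    """Full-platform two-feet scene used by the mosaic tests."""
    return phantom.make_platform_scene(canvas=(600, 720), seed=0)


@pytest.fixture(scope="session")
def distorted_tile_set(platform_scene):
    """Tiles with radial distortion and photometric offsets plus landmarks."""
    cams = {
        "UL": mosaic.CameraModel(k1=0.05),
        "UR": mosaic.CameraModel(k1=0.05, contrast_gain=1.1, intensity_offset=15.0),
        "LL": mosaic.CameraModel(k1=0.05, contrast_gain=0.9, intensity_offset=-15.0),
        "LR": mosaic.CameraModel(k1=0.05, contrast_gain=0.9, intensity_offset=-15.0),
    }
    cams = {
        tid: dataclasses.replace(c, tile_origin=None) for tid, c in cams.items()
    }
    tiles, landmarks, dotted = phantom.split_into_tiles(
        platform_scene, cams, overlap_px=16, n_landmarks=4, seed=3)
    return tiles, landmarks, dotted


@pytest.fixture(scope="session")
def gait_sequence():
    """Three-step phantom walk with ground truth."""
    frames, gt = phantom.make_gait_sequence(
        phantom.FootShapeParams(), [5.0, -7.0, 4.0],
        step_width_px=30.0, frames_per_step=6)
    return frames, gt


@pytest.fixture(scope="session")
def sway_sequence():
    """Isotropic sway sequence (sigma^2 = 25 px^2, 600 frames)."""
    params = phantom.SwayParams(cov_xx=25.0, cov_yy=25.0, n_frames=600, seed=11)
    frames, cop = phantom.make_sway_sequence(params)
    return frames, cop, params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
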