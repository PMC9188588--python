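"""Shared fixtures: small synthetic cameras and a mid-size calibration run."""

from dataclasses import replace

import numpy as np
import pytest

import darkcal as dc
from darkcal.experiments import simulate_pixel_stats


@pytest.fixture(scope="session")
def small_camera() -> dc.CameraGroundTruth:
    """16x16 camera without hot pixels, for fast statistical checks."""
    return dc.make_synthetic_camera((16, 16), hot_pixel_fraction=0.0, seed=101)


@pytest.fixture(scope="session")
def hot_camera() -> dc.CameraGroundTruth:
    """36x36 camera with one strong planted hot pixel at (17, 18)."""
    gt = dc.make_synthetic_camera((36, 36), hot_pixel_fraction=0.0, seed=202)
    dcm = gt.dark_current.copy()
    dcm[17, 18] = np.median(dcm) * 100.0
    return replace(gt, dark_current=dcm, hot_pixels=((17, 18),))


@pytest.fixture(scope="session")
def calibration_run(small_camera):
    """A moderately deep calibration of the small camera (5 times, 3000
    frames each): (camera, stats, calibration result)."""
    times = (0.001, 0.010, 0.050, 0.100, 0.500)
    stats = simulate_pixel_stats(small_camera, times, 3000, seed=77)
    cal = dc.calibrate(stats, bit_depth=small_camera.bit_depth)
    return small_camera, stats, cal


def single_pixel_camera(baseline=100.0, gain=2.0, dark_current=50.0, read_noise=1.0):
    one = np.ones((1, 1))
    return dc.CameraGroundTruth(
        baseline=baseline * one,
        dark_current=dark_current * one,
        read_noise=read_noise * one,
        gain=gain * one,
        flatfield=one.copy(),
    )
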