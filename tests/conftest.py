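from __future__ import annotations

import numpy as np
import pytest

from gmaselect import MotionSeries, PoseSeries
from gmaselect.pose_io import N_KEYPOINTS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024012)


def make_pose_series(
    rng: np.random.Generator,
    n_frames: int = 10,
    sample_rate_hz: float = 1.0,
    video_id: str = "vid",
) -> PoseSeries:
    """A random but valid pose series within a 1280x720 frame."""
    coords = np.empty((n_frames, N_KEYPOINTS, 2))
    coords[:, :, 0] = rng.uniform(0, 1279, size=(n_frames, N_KEYPOINTS))
    coords[:, :, 1] = rng.uniform(0, 719, size=(n_frames, N_KEYPOINTS))
    return PoseSeries(
        video_id=video_id,
        times=np.arange(n_frames) / sample_rate_hz,
        coords=coords,
        confidence=rng.uniform(0, 1, size=(n_frames, N_KEYPOINTS)).round(6),
        sample_rate_hz=sample_rate_hz,
    )


def make_motion(
    values, sample_rate_hz: float = 1.0, video_id: str = "vid", t0_s: float = 0.0
) -> MotionSeries:
    return MotionSeries(
        video_id=video_id,
        values=np.asarray(values, dtype=float),
        sample_rate_hz=sample_rate_hz,
        t0_s=t0_s,
    )


def constant_pose_coords(value_xy=(100.0, 100.0)) -> np.ndarray:
    """(17, 2) coordinates all at one point — a perfectly still pose."""
    return np.tile(np.asarray(value_xy, dtype=float), (N_KEYPOINTS, 1))
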