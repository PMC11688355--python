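"""Synthetic pose series with planted motion bursts and simulated raters.

The generator emulates the study conditions under which the selector is
meant to operate: hour-long supine recordings of a preterm infant sampled at
one pose per second, with a handful of high-motion episodes ("bursts") of
roughly one-minute duration standing out of low-amplitude pose-estimator
jitter. Simulated experts are jittered oracles — they annotate the true
bursts with Gaussian perturbations of the start time — which is the minimal
rater model that exercises the matching, dice and precision machinery
nontrivially.

All randomness derives from a single integer seed, split hierarchically per
video and per expert, so that e.g. adding an expert never perturbs the pose
streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .intervals import TimeInterval
from .pose_io import ExpertAnnotation, N_KEYPOINTS, PoseSeries

#: A supine 17-keypoint skeleton template (COCO-17 order), as fractions of
#: the frame size, centred on an infant lying on its back.
_SUPINE_TEMPLATE_FRAC = np.array(
    [
        (0.50, 0.28),  # nose
        (0.48, 0.26),  # left_eye
        (0.52, 0.26),  # right_eye
        (0.46, 0.28),  # left_ear
        (0.54, 0.28),  # right_ear
        (0.42, 0.40),  # left_shoulder
        (0.58, 0.40),  # right_shoulder
        (0.36, 0.50),  # left_elbow
        (0.64, 0.50),  # right_elbow
        (0.32, 0.58),  # left_wrist
        (0.68, 0.58),  # right_wrist
        (0.45, 0.62),  # left_hip
        (0.55, 0.62),  # right_hip
        (0.40, 0.74),  # left_knee
        (0.60, 0.74),  # right_knee
        (0.38, 0.86),  # left_ankle
        (0.62, 0.86),  # right_ankle
    ]
)


@dataclass(frozen=True)
class BurstSpec:
    """A planted high-motion episode.

    ``amplitude_px`` is the per-frame, per-keypoint displacement scale: inside
    the burst each keypoint receives an extra random-direction offset of
    magnitude ``|Normal(amplitude_px, amplitude_px / 4)|`` every frame.
    """

    start_s: float
    duration_s: float
    amplitude_px: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ConfigError("burst start must be >= 0")
        if self.duration_s <= 0:
            raise ConfigError("burst duration must be positive")
        if self.amplitude_px <= 0:
            raise ConfigError("burst amplitude must be positive")

    @property
    def interval(self) -> TimeInterval:
        return TimeInterval(self.start_s, self.start_s + self.duration_s)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one video's poses and its raters.

    Defaults mirror the target recording protocol: hour-long videos at one
    pose per second in 1280x720 frames, four raters each selecting five
    sequences, with a rater start-time jitter of 5 s.
    """

    video_length_s: int = 3600
    sample_rate_hz: float = 1.0
    baseline_jitter_px: float = 1.0
    bursts: tuple[BurstSpec, ...] = field(default_factory=tuple)
    frame_width_px: int = 1280
    frame_height_px: int = 720
    n_experts: int = 4
    expert_jitter_s: float = 5.0
    ns_per_expert: int = 5
    seed: int = 0
    video_id: str = "sim"

    def __post_init__(self) -> None:
        if self.video_length_s <= 0 or self.sample_rate_hz <= 0:
            raise ConfigError("video length and sample rate must be positive")
        if self.baseline_jitter_px < 0 or self.expert_jitter_s < 0:
            raise ConfigError("noise scales must be >= 0")
        if self.n_experts < 0 or self.ns_per_expert < 1:
            raise ConfigError("n_experts must be >= 0 and ns_per_expert >= 1")
        if self.frame_width_px <= 0 or self.frame_height_px <= 0:
            raise ConfigError("frame dimensions must be positive")
        for b in self.bursts:
            if b.start_s + b.duration_s > self.video_length_s + 1e-9:
                raise ConfigError(
                    f"burst [{b.start_s}, {b.start_s + b.duration_s}) extends "
                    f"past the {self.video_length_s} s video"
                )
        ivs = sorted((b.start_s, b.start_s + b.duration_s) for b in self.bursts)
        for (s0, e0), (s1, e1) in zip(ivs[:-1], ivs[1:]):
            if s1 < e0:
                warnings.warn(
                    f"bursts [{s0}, {e0}) and [{s1}, {e1}) overlap",
                    stacklevel=2,
                )


def _pose_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _expert_rng(config: SimulationConfig, expert_index: int) -> np.random.Generator:
    # per-expert stream: adding an expert never perturbs existing streams
    return np.random.default_rng([config.seed, 1, expert_index])


def generate_pose_series(
    config: SimulationConfig,
) -> tuple[PoseSeries, list[TimeInterval]]:
    """Generate a pose series and the ground-truth burst intervals.

    The 17 keypoints sit on a fixed supine skeleton template centred in the
    frame. Every frame adds Gaussian position jitter of
    ``baseline_jitter_px``; frames inside a burst additionally receive an
    independent random-direction offset with magnitude
    ``|Normal(amplitude_px, amplitude_px / 4)|`` per keypoint. Coordinates
    are clamped to the frame. Bit-reproducible given the seed.
    """
    rng = _pose_rng(config)
    n_frames = int(round(config.video_length_s * config.sample_rate_hz)) + 1
    times = np.arange(n_frames) / config.sample_rate_hz
    frame_size = np.array([config.frame_width_px, config.frame_height_px], float)
    template = _SUPINE_TEMPLATE_FRAC * frame_size  # (17, 2)

    coords = template[None, :, :] + rng.normal(
        0.0, config.baseline_jitter_px, size=(n_frames, N_KEYPOINTS, 2)
    )
    for burst in config.bursts:
        in_burst = (times >= burst.start_s - 1e-9) & (
            times < burst.start_s + burst.duration_s - 1e-9
        )
        nb = int(in_burst.sum())
        if nb == 0:
            continue
        magnitude = np.abs(
            rng.normal(burst.amplitude_px, burst.amplitude_px / 4.0,
                       size=(nb, N_KEYPOINTS))
        )
        angle = rng.uniform(0.0, 2.0 * np.pi, size=(nb, N_KEYPOINTS))
        offset = magnitude[:, :, None] * np.stack(
            (np.cos(angle), np.sin(angle)), axis=-1
        )
        coords[in_burst] += offset

    np.clip(coords[:, :, 0], 0.0, frame_size[0] - 1.0, out=coords[:, :, 0])
    np.clip(coords[:, :, 1], 0.0, frame_size[1] - 1.0, out=coords[:, :, 1])

    series = PoseSeries(
        video_id=config.video_id,
        times=times,
        coords=coords,
        confidence=np.ones((n_frames, N_KEYPOINTS)),
        sample_rate_hz=config.sample_rate_hz,
        frame_width_px=config.frame_width_px,
        frame_height_px=config.frame_height_px,
    )
    return series, [b.interval for b in config.bursts]


def generate_expert_annotations(
    bursts: Sequence[BurstSpec], config: SimulationConfig
) -> list[ExpertAnnotation]:
    """Simulate raters as jittered oracles over the planted bursts.

    Each expert annotates the ``ns_per_expert`` largest-amplitude bursts,
    perturbing every start by ``Normal(0, expert_jitter_s)`` and clamping so
    the interval stays inside the video. When fewer bursts exist than
    sequences requested, the expert pads with uniformly placed random
    intervals (flagged with a warning). Deterministic given the seed;
    distinct experts use distinct sub-streams.
    """
    order = sorted(
        range(len(bursts)),
        key=lambda i: (-bursts[i].amplitude_px, bursts[i].start_s),
    )
    chosen = [bursts[i] for i in order[: config.ns_per_expert]]
    n_pad = config.ns_per_expert - len(chosen)
    if n_pad > 0:
        warnings.warn(
            f"only {len(chosen)} bursts for {config.ns_per_expert} sequences "
            f"per expert; padding with {n_pad} random intervals",
            stacklevel=2,
        )
    pad_duration = (
        float(np.mean([b.duration_s for b in chosen])) if chosen else 60.0
    )

    annotations = []
    for e in range(config.n_experts):
        rng = _expert_rng(config, e)
        intervals = []
        for b in chosen:
            start = b.start_s + rng.normal(0.0, config.expert_jitter_s)
            start = float(
                np.clip(start, 0.0, config.video_length_s - b.duration_s)
            )
            intervals.append(TimeInterval(start, start + b.duration_s))
        for _ in range(n_pad):
            start = float(
                rng.uniform(0.0, config.video_length_s - pad_duration)
            )
            intervals.append(TimeInterval(start, start + pad_duration))
        annotations.append(
            ExpertAnnotation(
                rater_id=f"expert_{e + 1}",
                video_id=config.video_id,
                intervals=tuple(intervals),
            )
        )
    return annotations


# ---------------------------------------------------------------------------
# multi-video studies
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class StudyData:
    """A full synthetic study: pose series, ground truth and annotations."""

    series: list[PoseSeries]
    truth: dict[str, list[TimeInterval]]
    annotations: list[ExpertAnnotation]
    configs: list[SimulationConfig]


def place_bursts(
    n: int,
    video_length_s: float,
    duration_s: float,
    min_gap_s: float,
    rng: np.random.Generator,
    amplitude_px: float = 20.0,
    amplitude_spread: float = 0.2,
) -> tuple[BurstSpec, ...]:
    """Place ``n`` non-overlapping bursts separated by at least ``min_gap_s``.

    Starts are drawn uniformly over all admissible configurations (sorted
    uniforms in the residual free space); amplitudes vary uniformly within
    ``amplitude_px * (1 ± amplitude_spread)`` so burst ranks are distinct.
    """
    occupied = n * duration_s + (n - 1) * min_gap_s
    free = video_length_s - occupied
    if free < 0:
        raise ConfigError(
            f"{n} bursts of {duration_s} s with {min_gap_s} s gaps do not fit "
            f"in {video_length_s} s"
        )
    offsets = np.sort(rng.uniform(0.0, free, size=n))
    starts = offsets + np.arange(n) * (duration_s + min_gap_s)
    amplitudes = amplitude_px * rng.uniform(
        1.0 - amplitude_spread, 1.0 + amplitude_spread, size=n
    )
    return tuple(
        BurstSpec(float(s), duration_s, float(a))
        for s, a in zip(starts, amplitudes)
    )


def generate_study(
    n_videos: int = 6,
    n_bursts: int = 5,
    burst_duration_s: float = 60.0,
    amplitude_px: float = 20.0,
    video_length_s: int = 3600,
    baseline_jitter_px: float = 1.0,
    sample_rate_hz: float = 1.0,
    n_experts: int = 4,
    expert_jitter_s: float = 5.0,
    min_separation_s: float = 60.0,
    seed: int = 0,
) -> StudyData:
    """Generate a multi-video study mirroring the evaluation protocol:
    several hour-long videos, a fixed number of one-minute bursts per video,
    and a panel of jittered raters annotating each video."""
    master = np.random.default_rng([seed, 2])
    series_list: list[PoseSeries] = []
    truth: dict[str, list[TimeInterval]] = {}
    annotations: list[ExpertAnnotation] = []
    configs: list[SimulationConfig] = []
    video_seeds = np.random.SeedSequence(seed).generate_state(n_videos) & 0x7FFFFFFF
    for v in range(n_videos):
        video_id = f"video_{v + 1}"
        bursts = place_bursts(
            n_bursts,
            video_length_s,
            burst_duration_s,
            min_separation_s,
            master,
            amplitude_px=amplitude_px,
        )
        config = SimulationConfig(
            video_length_s=video_length_s,
            sample_rate_hz=sample_rate_hz,
            baseline_jitter_px=baseline_jitter_px,
            bursts=bursts,
            n_experts=n_experts,
            expert_jitter_s=expert_jitter_s,
            ns_per_expert=n_bursts,
            seed=int(video_seeds[v]),
            video_id=video_id,
        )
        series, intervals = generate_pose_series(config)
        series_list.append(series)
        truth[video_id] = intervals
        annotations.extend(generate_expert_annotations(bursts, config))
        configs.append(config)
    return StudyData(
        series=series_list, truth=truth, annotations=annotations, configs=configs
    )
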