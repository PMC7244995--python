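"""Synthetic severity-graded finger-to-nose videos and simulated ratings.

The generator emulates the standardized clinical recording: a fingertip
moves from an abducted-arm start position toward a nose target, with tremor
and clumsiness that grow with the limb-ataxia grade (ordinal 0-4, where 0 is
no ataxia and 4 means most functions are very difficult).  A video is a
sequence of RGB(-D) frames showing an arm segment from a fixed shoulder
anchor to the current fingertip position over a per-subject textured
background.  Everything is a pure function of its spec plus a seed.

Kinematics: the fingertip path is linear interpolation start -> end, plus a
sinusoidal tremor applied perpendicular to the path
(``amplitude * sin(2 pi * frequency * t / n)``), plus isotropic Gaussian
jitter, plus an optional along-path overshoot past the nose.  The tremor
amplitude and jitter scale linearly with the grade, so grade 0 is an exact
straight line and the mean perpendicular path deviation is strictly
increasing in grade — the ordinal structure the clinical scale implies.

Frame coordinates are (row, col), origin top-left, 0-based; intensities are
quantized to the 8-bit grid (k/255) so PNG round trips are lossless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .agreement import NOT_RATABLE, RatingTable

#: tremor pixels per grade step and jitter SD pixels per grade step at 64x64
TREMOR_PX_PER_GRADE = 2.0
JITTER_SD_PER_GRADE = 0.5
OVERSHOOT_PROB_PER_GRADE = 0.1
BASE_RESOLUTION = 64

GRADES = (0, 1, 2, 3, 4)


def _check_grade(grade: int) -> int:
    grade = int(grade)
    if grade not in GRADES:
        raise ValueError(f"ataxia grade must be in {GRADES}, got {grade}")
    return grade


@dataclass(frozen=True)
class SubjectIdentity:
    """Nuisance identity features a privacy-preserving code should discard."""

    subject_id: str
    limb_thickness: float = 5.0  # pixels
    skin_tone: tuple[float, float, float] = (0.55, 0.42, 0.34)
    background_pattern_seed: int = 0
    nose_target: tuple[float, float] = (16.0, 48.0)  # (row, col)
    body_depth_offset: float = 0.6

    def __post_init__(self):
        if self.limb_thickness < 1:
            raise ValueError("limb_thickness must be >= 1 pixel")
        if not all(0.0 <= c <= 1.0 for c in self.skin_tone):
            raise ValueError("skin_tone components must be in [0, 1]")
        if not 0.0 <= self.body_depth_offset <= 1.0:
            raise ValueError("body_depth_offset must be in [0, 1]")


@dataclass(frozen=True)
class TrajectorySpec:
    """Kinematic parameters of one finger-to-nose execution."""

    n_frames: int
    start_point: tuple[float, float]
    end_point: tuple[float, float]
    tremor_amplitude: float = 0.0  # pixels, perpendicular to the path
    tremor_frequency: float = 3.0  # cycles over the whole trajectory
    jitter_sd: float = 0.0  # pixels
    overshoot_prob: float = 0.0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("a trajectory needs n_frames >= 2")
        if self.tremor_amplitude < 0 or self.jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.overshoot_prob <= 1.0:
            raise ValueError("overshoot_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticVideoSpec:
    """Full ground truth of one simulated video."""

    subject: SubjectIdentity
    grade: int
    trajectory: TrajectorySpec
    resolution: int = BASE_RESOLUTION
    channels: int = 4
    seed: int = 0

    def __post_init__(self):
        _check_grade(self.grade)
        r = self.resolution
        if r < 8 or (r & (r - 1)) != 0:
            raise ValueError("resolution must be a power of two >= 8")
        if self.channels not in (3, 4):
            raise ValueError("channels must be 3 (RGB) or 4 (RGB-D)")
        nr, nc = self.subject.nose_target
        if not (0 <= nr < r and 0 <= nc < r):
            raise ValueError("nose_target must lie inside the frame")


@dataclass(frozen=True)
class RaterModel:
    """A simulated neurologist: ordinal rating with bias and miscoding noise.

    A rating is clip(round(true_grade + bias + N(0, miscode_sd)), 0, 4),
    replaced by the not-ratable marker with probability not_ratable_prob.
    """

    bias: float = 0.0
    miscode_sd: float = 0.0
    not_ratable_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.miscode_sd < 0:
            raise ValueError("miscode_sd must be non-negative")
        if not 0.0 <= self.not_ratable_prob <= 1.0:
            raise ValueError("not_ratable_prob must be in [0, 1]")


def grade_trajectory_spec(
    grade: int,
    resolution: int = BASE_RESOLUTION,
    n_frames: int = 30,
    start_point: tuple[float, float] | None = None,
    end_point: tuple[float, float] | None = None,
) -> TrajectorySpec:
    """Trajectory parameters implied by an ataxia grade.

    Tremor amplitude and jitter grow linearly with the grade (2 px and
    0.5 px per step at 64x64, scaled with resolution); grade 0 is noiseless.
    """
    grade = _check_grade(grade)
    scale = resolution / BASE_RESOLUTION
    if start_point is None:
        start_point = (0.55 * resolution, 0.12 * resolution)
    if end_point is None:
        end_point = (0.25 * resolution, 0.75 * resolution)
    return TrajectorySpec(
        n_frames=n_frames,
        start_point=start_point,
        end_point=end_point,
        tremor_amplitude=TREMOR_PX_PER_GRADE * grade * scale,
        tremor_frequency=3.0,
        jitter_sd=JITTER_SD_PER_GRADE * grade * scale,
        overshoot_prob=OVERSHOOT_PROB_PER_GRADE * grade,
    )


def simulate_trajectory(spec: TrajectorySpec, seed: int) -> np.ndarray:
    """Fingertip positions, shape (n_frames, 2) in (row, col) coordinates.

    Deterministic given (spec, seed).  The first point equals the start
    exactly; the last point is within jitter_sd + tremor_amplitude of the
    end point (the final jitter draw is norm-clipped to jitter_sd).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_frames
    start = np.asarray(spec.start_point, dtype=np.float64)
    end = np.asarray(spec.end_point, dtype=np.float64)
    u = np.arange(n) / (n - 1)

    # along-path progress, possibly overshooting the nose mid-course
    progress = u.copy()
    if rng.random() < spec.overshoot_prob:
        progress = u + 0.6 * u * np.sin(np.pi * u)

    direction = end - start
    length = np.linalg.norm(direction)
    if length == 0:
        unit = np.array([0.0, 1.0])
    else:
        unit = direction / length
    perp = np.array([-unit[1], unit[0]])

    points = start[None, :] + progress[:, None] * direction[None, :]
    tremor = spec.tremor_amplitude * np.sin(2 * np.pi * spec.tremor_frequency * u)
    points = points + tremor[:, None] * perp[None, :]

    jitter = rng.normal(0.0, spec.jitter_sd, size=(n, 2)) if spec.jitter_sd else np.zeros((n, 2))
    jitter[0] = 0.0  # the start position is held exactly
    if spec.jitter_sd:
        jn = np.linalg.norm(jitter[-1])
        if jn > spec.jitter_sd:  # keep the endpoint within its tolerance
            jitter[-1] *= spec.jitter_sd / jn
    return points + jitter


def path_deviation(points: np.ndarray, start, end) -> float:
    """Mean absolute perpendicular deviation of a path from the line start-end."""
    start = np.asarray(start, dtype=np.float64)
    end = np.asarray(end, dtype=np.float64)
    direction = end - start
    length = np.linalg.norm(direction)
    if length == 0:
        return float(np.mean(np.linalg.norm(points - start, axis=1)))
    unit = direction / length
    perp = np.array([-unit[1], unit[0]])
    return float(np.mean(np.abs((points - start) @ perp)))


def _background(subject: SubjectIdentity, resolution: int) -> np.ndarray:
    """Low-contrast per-subject texture (coarse noise, bilinearly enlarged)."""
    rng = np.random.default_rng(subject.background_pattern_seed)
    coarse = rng.uniform(0.62, 0.78, size=(8, 8))
    tile = np.kron(coarse, np.ones((resolution // 8, resolution // 8)))
    tint = rng.uniform(0.95, 1.05, size=3)
    bg = np.clip(tile[..., None] * tint[None, None, :], 0.0, 1.0)
    return bg


def render_frame(
    subject: SubjectIdentity,
    fingertip,
    resolution: int = BASE_RESOLUTION,
    channels: int = 4,
) -> np.ndarray:
    """Render one frame: arm from the shoulder anchor to the fingertip.

    Returns (resolution, resolution, channels) float32 in [0, 1], quantized
    to the 8-bit grid.  With channels=4 the last channel is a synthetic
    depth map: background at 0, the arm at body_depth_offset, and the
    fingertip raised toward the camera.
    """
    fingertip = np.asarray(fingertip, dtype=np.float64)
    if not (0 <= fingertip[0] <= resolution - 1 and 0 <= fingertip[1] <= resolution - 1):
        warnings.warn("fingertip outside frame bounds; clipping", stacklevel=2)
        fingertip = np.clip(fingertip, 0, resolution - 1)

    shoulder = np.array([0.82 * resolution, 0.06 * resolution])
    rows, cols = np.mgrid[0:resolution, 0:resolution].astype(np.float64)
    pix = np.stack([rows, cols], axis=-1)

    # distance from every pixel to the shoulder-fingertip segment
    seg = fingertip - shoulder
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        t = np.zeros_like(rows)
    else:
        t = np.clip(((pix - shoulder) @ seg) / seg_len2, 0.0, 1.0)
    closest = shoulder[None, None, :] + t[..., None] * seg[None, None, :]
    dist = np.linalg.norm(pix - closest, axis=-1)
    arm_mask = dist <= subject.limb_thickness / 2.0
    tip_dist = np.linalg.norm(pix - fingertip[None, None, :], axis=-1)
    tip_mask = tip_dist <= max(subject.limb_thickness * 0.75, 1.5)
    nose = np.asarray(subject.nose_target, dtype=np.float64)
    nose_mask = np.linalg.norm(pix - nose[None, None, :], axis=-1) <= 1.5

    frame = _background(subject, resolution)
    tone = np.asarray(subject.skin_tone)
    frame[arm_mask] = tone
    frame[tip_mask] = np.clip(tone * 0.8, 0.0, 1.0)  # darker fingertip marker
    frame[nose_mask] = (0.15, 0.15, 0.15)

    if channels == 4:
        depth = np.zeros((resolution, resolution))
        depth[arm_mask] = subject.body_depth_offset
        depth[tip_mask] = min(1.0, subject.body_depth_offset + 0.3)
        frame = np.concatenate([frame, depth[..., None]], axis=-1)
    elif channels != 3:
        raise ValueError("channels must be 3 or 4")

    return (np.round(frame * 255.0) / 255.0).astype(np.float32)


def simulate_video(spec: SyntheticVideoSpec) -> tuple[np.ndarray, SyntheticVideoSpec]:
    """Render a full video; bitwise reproducible given the spec's seed."""
    traj_spec = spec.trajectory
    points = simulate_trajectory(traj_spec, seed=spec.seed)
    points = np.clip(points, 0, spec.resolution - 1)
    frames = np.stack(
        [
            render_frame(spec.subject, p, spec.resolution, spec.channels)
            for p in points
        ]
    )
    return frames, spec


def random_subject(rng: np.random.Generator, subject_id: str,
                   resolution: int = BASE_RESOLUTION) -> SubjectIdentity:
    """Draw plausible identity nuisance features for one subject."""
    base = rng.uniform(0.35, 0.6)
    tone = np.clip(base * np.array([1.0, 0.8, 0.68]) + rng.normal(0, 0.02, 3), 0, 1)
    return SubjectIdentity(
        subject_id=subject_id,
        limb_thickness=float(rng.uniform(4.0, 7.0)) * resolution / BASE_RESOLUTION,
        skin_tone=tuple(float(c) for c in tone),
        background_pattern_seed=int(rng.integers(0, 2**31 - 1)),
        nose_target=(
            float(rng.uniform(0.2, 0.3) * resolution),
            float(rng.uniform(0.7, 0.8) * resolution),
        ),
        body_depth_offset=float(rng.uniform(0.5, 0.7)),
    )


def simulate_dataset(
    n_videos: int,
    seed: int,
    grades=None,
    resolution: int = BASE_RESOLUTION,
    channels: int = 4,
    n_frames: int = 30,
    n_subjects: int | None = None,
) -> list[tuple[np.ndarray, SyntheticVideoSpec]]:
    """Simulate a dataset of videos with grades cycling through 0-4.

    Each video gets its own subject unless `n_subjects` is given, in which
    case subjects are reused cyclically (useful for cross-subject latent
    analyses).
    """
    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    rng = np.random.default_rng(seed)
    if grades is None:
        grades = [GRADES[i % len(GRADES)] for i in range(n_videos)]
    if len(grades) != n_videos:
        raise ValueError("grades must have one entry per video")
    n_subjects = n_subjects or n_videos
    subjects = [
        random_subject(rng, f"subj{j:03d}", resolution) for j in range(n_subjects)
    ]
    out = []
    for i in range(n_videos):
        subject = subjects[i % n_subjects]
        traj = grade_trajectory_spec(
            grades[i],
            resolution,
            n_frames,
            end_point=subject.nose_target,
        )
        spec = SyntheticVideoSpec(
            subject=subject,
            grade=int(grades[i]),
            trajectory=traj,
            resolution=resolution,
            channels=channels,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(simulate_video(spec))
    return out


def simulate_ratings(
    true_grades,
    raters,
    video_ids=None,
    condition: str = "original",
) -> RatingTable:
    """Simulate an ordinal rating table (videos x raters).

    Each cell is clip(round(g + bias + N(0, miscode_sd)), 0, 4), or the
    not-ratable marker with probability `not_ratable_prob`; deterministic
    given each rater's seed.
    """
    true_grades = [_check_grade(g) for g in true_grades]
    raters = list(raters)
    if not true_grades or not raters:
        raise ValueError("need at least one video and one rater")
    if video_ids is None:
        video_ids = [f"video{i:03d}" for i in range(len(true_grades))]
    n = len(true_grades)
    columns = {}
    for r_idx, rater in enumerate(raters):
        rng = np.random.default_rng(rater.seed)
        noise = rng.normal(0.0, rater.miscode_sd, size=n) if rater.miscode_sd else 0.0
        vals = np.clip(np.round(np.asarray(true_grades) + rater.bias + noise), 0, 4)
        nr = rng.random(n) < rater.not_ratable_prob
        col = [NOT_RATABLE if m else int(v) for v, m in zip(vals, nr)]
        columns[f"rater{r_idx:02d}"] = col
    return RatingTable.from_columns(columns, video_ids, condition=condition)
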