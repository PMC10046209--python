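"""Static and dynamic Gestalt-grouping stimuli.

The static task shows 12 equal dots arranged in three or four columns
(grouping by proximity) or the same 12 dots placed uniformly at random
over the same area (the scrambled control).  The dynamic task arranges
the 12 dots in three columns and translates them rigidly in a common
direction (grouping by proximity and common fate); its scrambled control
gives every dot an independent random direction at the same speed.
Grouped and scrambled variants of a condition share the bounding box and
dot diameter exactly, so only the spatial organisation differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clip import FIGURE, StimulusClip

MOTION_DIRECTIONS = {
    "up": (0.0, 1.0),
    "down": (0.0, -1.0),
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
}

#: Column-alignment score below which a random dot placement counts as
#: "not grouped by proximity"; used by the scrambled-static rejection
#: rule and as the default decision criterion of the static detector.
DEFAULT_STATIC_CRITERION = 0.85

_MAX_RESAMPLE = 100


@dataclass
class GroupingParams:
    """Geometry of the 12-dot grouping stimulus (deg of visual angle)."""

    n_dots: int = 12
    n_columns: int = 3
    size: float = 16.0
    dot_diameter: float = 0.5
    column_spacing: float | None = None
    row_spacing: float | None = None
    fps: float = 30.0
    duration: float = 1.0  # matches one walker gait cycle

    def __post_init__(self) -> None:
        if self.n_dots != 12:
            raise ValueError("the grouping stimulus uses exactly 12 dots")
        if self.n_columns not in (3, 4):
            raise ValueError(f"n_columns must be 3 or 4, got {self.n_columns}")
        if self.n_dots % self.n_columns:
            raise ValueError("n_dots must be divisible by n_columns")
        if self.size <= 0 or self.dot_diameter <= 0:
            raise ValueError("size and dot_diameter must be > 0")

    @property
    def n_rows(self) -> int:
        return self.n_dots // self.n_columns

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass
class MotionParams:
    """Common-fate translation of the dynamic grouping stimulus."""

    direction: str = "up"
    speed: float = 9.5  # deg/s at the reference size; scaled with magnification

    def __post_init__(self) -> None:
        if self.direction not in MOTION_DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(MOTION_DIRECTIONS)}")
        if self.speed <= 0:
            raise ValueError("speed must be > 0")


def _grid_positions(params: GroupingParams) -> np.ndarray:
    """Centred column grid of the grouped variant, shape (12, 2)."""
    margin = 0.1 * params.size
    half = params.size / 2.0 - margin
    if params.column_spacing is not None:
        xs = (np.arange(params.n_columns) - (params.n_columns - 1) / 2.0) * params.column_spacing
    else:
        xs = np.linspace(-half, half, params.n_columns)
    if params.row_spacing is not None:
        ys = (np.arange(params.n_rows) - (params.n_rows - 1) / 2.0) * params.row_spacing
    else:
        ys = np.linspace(-half, half, params.n_rows)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _bbox(params: GroupingParams) -> tuple[float, float, float, float]:
    half = params.size / 2.0
    return (-half, -half, half, half)


def _make_clip(params: GroupingParams, task: str, truth: str,
               positions: np.ndarray, meta: dict) -> StimulusClip:
    n = params.n_dots
    return StimulusClip(
        task=task,
        truth=truth,
        fps=params.fps,
        size=params.size,
        eccentricity=0.0,
        bbox=_bbox(params),
        positions=positions,
        diameters=np.full(n, params.dot_diameter),
        provenance=np.array([FIGURE] * n, dtype=object),
        noise_count=0,
        meta=meta,
    )


def _sample_unaligned(params: GroupingParams, rng: np.random.Generator,
                      criterion: float) -> np.ndarray:
    """Uniform 12-dot placement rejected until it is not column-like.

    Resamples until the column-alignment score of the placement falls
    below ``criterion`` so the scrambled variant can never be mistaken
    for a proximity-grouped stimulus by the detector contract.
    """
    from .detectors import column_score  # local import: detectors use clips

    x0, y0, x1, y1 = _bbox(params)
    for _ in range(_MAX_RESAMPLE):
        pos = np.column_stack([
            rng.uniform(x0, x1, params.n_dots),
            rng.uniform(y0, y1, params.n_dots),
        ])
        probe = _make_clip(params, "static", "scrambled", pos[None, :, :], {})
        if column_score(probe) < criterion:
            return pos
    raise RuntimeError(
        f"could not sample an unaligned dot placement in {_MAX_RESAMPLE} attempts"
    )


def generate_static_grouping(params: GroupingParams | None = None,
                             truth: str = "grouped",
                             seed=None,
                             criterion: float = DEFAULT_STATIC_CRITERION) -> StimulusClip:
    """Generate the static proximity-grouping stimulus or its control.

    ``grouped`` places the 12 dots on an ``n_columns x (12/n_columns)``
    grid; ``scrambled`` draws them uniformly over the same bounding box,
    resampling until the placement is not column-aligned.  Dot diameter
    and bounding box are identical across the two variants.
    """
    params = params or GroupingParams()
    if truth not in ("grouped", "scrambled"):
        raise ValueError(f"truth must be 'grouped' or 'scrambled', got {truth!r}")
    rng = np.random.default_rng(seed)
    if truth == "grouped":
        pos0 = _grid_positions(params)
    else:
        pos0 = _sample_unaligned(params, rng, criterion)
    pos = np.repeat(pos0[None, :, :], params.n_frames, axis=0)
    return _make_clip(params, "static", truth, pos,
                      {"n_columns": params.n_columns})


def generate_dynamic_grouping(params: GroupingParams | None = None,
                              motion: MotionParams | None = None,
                              truth: str = "grouped",
                              seed=None) -> StimulusClip:
    """Generate the common-fate grouping stimulus or its control.

    The grouped variant translates a three-column grid rigidly at
    ``motion.speed`` in ``motion.direction``; the scrambled variant moves
    each of the 12 dots at the same speed in an independent uniformly
    random direction from a random start in the bounding box.  The clip
    duration equals the walker gait cycle.
    """
    params = params or GroupingParams()
    motion = motion or MotionParams()
    if truth not in ("grouped", "scrambled"):
        raise ValueError(f"truth must be 'grouped' or 'scrambled', got {truth!r}")
    rng = np.random.default_rng(seed)
    t = (np.arange(params.n_frames) / params.fps)[:, None, None]
    if truth == "grouped":
        if params.n_columns != 3:
            raise ValueError("the grouped dynamic stimulus uses 3 columns")
        pos0 = _grid_positions(params)
        v = motion.speed * np.asarray(MOTION_DIRECTIONS[motion.direction])
        vel = np.repeat(v[None, :], params.n_dots, axis=0)
        meta = {"motion_direction": motion.direction, "speed": motion.speed}
    else:
        x0, y0, x1, y1 = _bbox(params)
        pos0 = np.column_stack([
            rng.uniform(x0, x1, params.n_dots),
            rng.uniform(y0, y1, params.n_dots),
        ])
        angles = rng.uniform(0.0, 2.0 * np.pi, params.n_dots)
        vel = motion.speed * np.column_stack([np.cos(angles), np.sin(angles)])
        meta = {"speed": motion.speed}
    pos = pos0[None, :, :] + vel[None, :, :] * t
    return _make_clip(params, "dynamic", truth, pos, meta)
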