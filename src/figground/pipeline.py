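"""Trial-level stimulus synthesis.

Bundles the per-task generator defaults and produces, for one trial of
the experiment, a complete clip: grouped or scrambled stimulus at the
reference size, embedded in the requested amount of matched visual
noise, then magnified and placed at its eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grouping import (GroupingParams, MotionParams, MOTION_DIRECTIONS,
                       generate_dynamic_grouping, generate_static_grouping)
from .layout import Layout, scale_to_layout
from .noise import NoiseParams, embed_noise
from .walker import DIRECTIONS, WalkerParams, generate_walker, scramble_walker
from .clip import StimulusClip


@dataclass
class StimulusConfig:
    """Generator defaults shared by detector calibration and experiments."""

    walker: WalkerParams = field(default_factory=WalkerParams)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    motion: MotionParams = field(default_factory=MotionParams)
    area_factor: float = 1.5
    randomize: bool = True  # draw walker direction/phase and motion direction per trial


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def make_trial_clip(task: str, truth: str, level: int, layout: Layout,
                    rng: np.random.Generator | int | None = None,
                    config: StimulusConfig | None = None) -> StimulusClip:
    """Synthesize the clip shown on a single trial.

    The figure is generated at the reference size, the ``level`` noise
    dots are embedded with motion statistics matched to the scrambled
    variant, and the whole field is scaled/translated to ``layout``.
    Walker direction and gait phase (and the common-fate direction of
    the dynamic task) are drawn per trial when ``config.randomize``.
    """
    config = config or StimulusConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    if task == "walker":
        params = config.walker
        if config.randomize:
            n = params.n_frames
            params = WalkerParams(
                gait_period=params.gait_period, fps=params.fps, height=params.height,
                direction=float(DIRECTIONS[rng.integers(len(DIRECTIONS))]),
                phase0=2.0 * np.pi * float(rng.integers(n)) / n,
                translate=params.translate, speed_target=params.speed_target,
                dot_diameter=params.dot_diameter, gait_table=params.gait_table,
            )
        clip = generate_walker(params)
        if truth == "scrambled":
            clip = scramble_walker(clip, seed=_seed_from(rng))
    elif task == "static":
        clip = generate_static_grouping(config.grouping, truth=truth, seed=_seed_from(rng))
    elif task == "dynamic":
        motion = config.motion
        if config.randomize and truth == "grouped":
            directions = sorted(MOTION_DIRECTIONS)
            motion = MotionParams(direction=directions[rng.integers(len(directions))],
                                  speed=motion.speed)
        clip = generate_dynamic_grouping(config.grouping, motion, truth=truth,
                                         seed=_seed_from(rng))
    else:
        raise ValueError(f"unknown task {task!r}")

    clip = embed_noise(clip, NoiseParams(count=level, area_factor=config.area_factor),
                       seed=_seed_from(rng))
    return scale_to_layout(clip, layout)
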