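"""Visual-noise embedding.

Noise dots share the perceptual qualities (size and motion statistics)
of the dots of the *scrambled* variant of the task at hand, and are
spread over an area linearly larger than the figure bounding box:

* static task -- noise dots are stationary;
* dynamic task -- noise dots move at the stimulus dot speed in
  independent uniformly random directions;
* walker task -- noise trajectories are drawn with replacement from the
  inverted-walker per-dot motion library (the y-negated displacement
  sequences of the 13 walker dots) with uniformly random start points.

Figure dots are never touched; embedding only appends noise dots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clip import NOISE, StimulusClip


@dataclass
class NoiseParams:
    """Amount and spatial extent of the visual noise.

    ``area_factor`` is the linear expansion of the noise field relative
    to the figure bounding box (1.5 by default: the noise covers the
    figure and extends half a stimulus beyond it on each axis).
    """

    count: int = 0
    area_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("noise count must be >= 0")
        if self.area_factor < 1.0:
            raise ValueError("area_factor must be >= 1")


def noise_field_bbox(clip: StimulusClip, area_factor: float) -> tuple[float, float, float, float]:
    """Figure bbox expanded linearly by ``area_factor`` about the centre."""
    cx, cy = clip.center
    x0, y0, x1, y1 = clip.bbox
    hx = (x1 - x0) / 2.0 * area_factor
    hy = (y1 - y0) / 2.0 * area_factor
    return (cx - hx, cy - hy, cx + hx, cy + hy)


def _walker_motion_library(clip: StimulusClip) -> np.ndarray:
    """Per-dot displacement sequences of the scrambled (inverted) walker.

    For a grouped clip the library is the y-negated displacement
    sequence of each figure dot; a scrambled clip already carries the
    inverted motion, so its displacements are used as-is.  Either way
    the speed profile matches the scrambled stimulus exactly.
    """
    disp = np.diff(clip.figure_positions, axis=0)
    if clip.truth == "grouped":
        disp = disp.copy()
        disp[:, :, 1] *= -1.0
    return disp


def _dynamic_speed(clip: StimulusClip) -> float:
    """Common dot speed of a dynamic clip, measured from the first dot."""
    d = clip.positions[1, 0] - clip.positions[0, 0]
    return float(np.linalg.norm(d) * clip.fps)


def embed_noise(clip: StimulusClip, noise: NoiseParams | None = None, seed=None) -> StimulusClip:
    """Append ``noise.count`` noise dots matched to the scrambled stimulus.

    Returns a new clip; with ``count == 0`` the result equals the input.
    Requires a clip that does not already contain noise.
    """
    noise = noise or NoiseParams()
    if clip.noise_count != 0:
        raise ValueError("clip already contains noise dots")
    if noise.count == 0:
        return clip.copy()
    rng = np.random.default_rng(seed)
    n = noise.count
    x0, y0, x1, y1 = noise_field_bbox(clip, noise.area_factor)
    starts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])

    if clip.task == "static":
        traj = np.repeat(starts[None, :, :], clip.n_frames, axis=0)
    elif clip.task == "dynamic":
        speed = _dynamic_speed(clip)
        angles = rng.uniform(0.0, 2.0 * np.pi, n)
        vel = speed * np.column_stack([np.cos(angles), np.sin(angles)])
        t = (np.arange(clip.n_frames) / clip.fps)[:, None, None]
        traj = starts[None, :, :] + vel[None, :, :] * t
    else:  # walker
        lib = _walker_motion_library(clip)
        idx = rng.integers(0, lib.shape[1], n)
        disp = lib[:, idx, :]
        traj = np.concatenate([starts[None, :, :], starts[None, :, :] + np.cumsum(disp, axis=0)])

    mean_diam = float(clip.diameters.mean())
    out = clip.copy()
    out.positions = np.concatenate([clip.positions, traj], axis=1)
    out.diameters = np.concatenate([clip.diameters, np.full(n, mean_diam)])
    out.provenance = np.concatenate([clip.provenance, np.array([NOISE] * n, dtype=object)])
    out.noise_count = n
    out.meta = dict(clip.meta, noise_area_factor=noise.area_factor)
    return out
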