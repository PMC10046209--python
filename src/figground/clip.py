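"""Dot-stimulus containers.

Every stimulus in this package is a :class:`StimulusClip`: an ordered
sequence of frames, each holding the same physical dots at positions
expressed in degrees of visual angle.  The coordinate convention is
fixation at the origin, x rightward positive, y upward positive.
Dot identity is positional -- dot ``k`` of frame ``i`` is the same
physical dot as dot ``k`` of frame ``j`` -- which lets trajectories be
stored as a dense ``(n_frames, n_dots, 2)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

FIGURE = "figure"
NOISE = "noise"
TASKS = ("static", "dynamic", "walker")
TRUTHS = ("grouped", "scrambled")


@dataclass(frozen=True)
class Dot:
    """A single dot of one frame, in degrees of visual angle."""

    x: float
    y: float
    diameter: float
    provenance: str

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"dot diameter must be > 0, got {self.diameter}")
        if self.provenance not in (FIGURE, NOISE):
            raise ValueError(f"provenance must be 'figure' or 'noise', got {self.provenance!r}")


@dataclass(frozen=True)
class Frame:
    """One time sample of a clip: time since clip start plus its dots."""

    t: float
    dots: tuple[Dot, ...]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("frame time must be >= 0")


@dataclass
class StimulusClip:
    """A timed dot stimulus.

    Parameters
    ----------
    task
        One of ``static``, ``dynamic``, ``walker``.
    truth
        ``grouped`` (the target object) or ``scrambled`` (its control).
    fps
        Frame rate in Hz.
    size
        Nominal angular size of the stimulus (deg).
    eccentricity
        Horizontal distance of the stimulus centre from fixation (deg).
    bbox
        Figure bounding box ``(xmin, ymin, xmax, ymax)`` in deg.
    positions
        Array ``(n_frames, n_dots, 2)`` of dot centres in deg.
    diameters
        Array ``(n_dots,)`` of dot diameters in deg.
    provenance
        Array ``(n_dots,)`` of ``"figure"`` / ``"noise"`` labels.
    noise_count
        Number of embedded noise dots (must equal the provenance count).
    meta
        Free-form provenance of the generator (direction, gait phase, ...).
    """

    task: str
    truth: str
    fps: float
    size: float
    eccentricity: float
    bbox: tuple[float, float, float, float]
    positions: np.ndarray
    diameters: np.ndarray
    provenance: np.ndarray
    noise_count: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.truth not in TRUTHS:
            raise ValueError(f"truth must be one of {TRUTHS}, got {self.truth!r}")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        self.positions = np.asarray(self.positions, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_dots, 2)")
        n_dots = self.positions.shape[1]
        if self.diameters.shape != (n_dots,) or self.provenance.shape != (n_dots,):
            raise ValueError("diameters/provenance must have one entry per dot")
        if np.any(self.diameters <= 0):
            raise ValueError("all dot diameters must be > 0")
        bad = set(self.provenance) - {FIGURE, NOISE}
        if bad:
            raise ValueError(f"unknown provenance labels: {bad}")
        if self.noise_count != int(np.sum(self.provenance == NOISE)):
            raise ValueError("noise_count does not match provenance labels")
        bbox = tuple(float(v) for v in self.bbox)
        if len(bbox) != 4 or bbox[0] >= bbox[2] or bbox[1] >= bbox[3]:
            raise ValueError("bbox must be (xmin, ymin, xmax, ymax) with positive extent")
        self.bbox = bbox

    # -- basic geometry -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def center(self) -> np.ndarray:
        """Geometric centre of the bounding box (the stimulus centre)."""
        x0, y0, x1, y1 = self.bbox
        return np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])

    @property
    def figure_mask(self) -> np.ndarray:
        return self.provenance == FIGURE

    @property
    def figure_positions(self) -> np.ndarray:
        return self.positions[:, self.figure_mask, :]

    def frame(self, i: int) -> Frame:
        """Materialize frame ``i`` as a :class:`Frame` of :class:`Dot` objects."""
        pos = self.positions[i]
        dots = tuple(
            Dot(float(x), float(y), float(d), str(p))
            for (x, y), d, p in zip(pos, self.diameters, self.provenance)
        )
        return Frame(t=float(i / self.fps), dots=dots)

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    # -- kinematics ------------------------------------------------------

    def displacements(self) -> np.ndarray:
        """Frame-to-frame displacement vectors, shape ``(n_frames - 1, n_dots, 2)``."""
        return np.diff(self.positions, axis=0)

    def speeds(self) -> np.ndarray:
        """Instantaneous dot speeds (deg/s), shape ``(n_frames - 1, n_dots)``."""
        return np.linalg.norm(self.displacements(), axis=2) * self.fps

    def mean_dot_speed(self) -> float:
        """Mean frame-to-frame speed over all dots and frames (deg/s)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.speeds().mean())

    def copy(self) -> "StimulusClip":
        return replace(
            self,
            positions=self.positions.copy(),
            diameters=self.diameters.copy(),
            provenance=self.provenance.copy(),
            meta=dict(self.meta),
        )
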