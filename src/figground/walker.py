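"""Parametric point-light walker.

A walking human figure is modelled as 13 joints (head, left/right
shoulder, elbow, hand, hip, knee, foot) moving in walker-centred 3-D
coordinates: a lateral axis ``l``, a vertical axis ``y`` and a forward
axis ``f`` (the walking direction).  Each joint trajectory is the sum of
a constant mean position and a small bank of sinusoidal harmonics of the
gait cycle -- pendular limb swing at the stride frequency plus a
double-frequency bob of the trunk.  Right-side joints are derived from
their left homologue by mirroring the lateral mean and advancing every
harmonic of order ``k`` by ``k*pi``, which makes homologous limbs move
in exact antiphase (a half-gait-period shift).

The 3-D gait is orthographically projected onto the display plane at one
of five azimuths (profile views at +/-90 deg, oblique at +/-45 deg,
frontal at 0 deg).  An overall kinematic gain on the oscillation
amplitudes is solved numerically so that the mean projected dot speed in
profile view equals the requested target (9.5 deg/s by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clip import FIGURE, StimulusClip

JOINTS = (
    "head",
    "l_shoulder", "r_shoulder",
    "l_elbow", "r_elbow",
    "l_hand", "r_hand",
    "l_hip", "r_hip",
    "l_knee", "r_knee",
    "l_foot", "r_foot",
)

DIRECTIONS = (-90.0, -45.0, 0.0, 45.0, 90.0)

#: Joint motion table for the left body side and the head, in
#: unit-height coordinates.  Each entry is ``mean (l, y, f)`` plus a list
#: of harmonics ``(k, (amp_l, amp_y, amp_f), (ph_l, ph_y, ph_f))``; the
#: displacement on each axis is ``sum_k amp * sin(k * theta + ph)`` with
#: ``theta`` the gait phase.  Right-side joints are derived automatically.
_PI = math.pi
DEFAULT_GAIT_TABLE: dict[str, dict] = {
    "head": {
        "mean": (0.0, 0.455, 0.0),
        "harm": [(1, (0.012, 0.0, 0.0), (0.0, 0.0, 0.0)),
                 (2, (0.0, 0.012, 0.008), (0.0, _PI / 2, 0.0))],
    },
    "l_shoulder": {
        "mean": (-0.10, 0.330, 0.0),
        # arms counter-swing relative to the ipsilateral leg -> phase pi
        "harm": [(1, (0.010, 0.0, 0.045), (0.0, 0.0, _PI)),
                 (2, (0.0, 0.010, 0.0), (0.0, _PI / 2, 0.0))],
    },
    "l_elbow": {
        "mean": (-0.13, 0.160, 0.0),
        "harm": [(1, (0.010, 0.018, 0.085), (0.0, _PI + 0.6, _PI)),
                 (2, (0.0, 0.0, 0.015), (0.0, 0.0, 0.4))],
    },
    "l_hand": {
        "mean": (-0.13, 0.010, 0.0),
        "harm": [(1, (0.012, 0.035, 0.150), (0.0, _PI + 1.0, _PI)),
                 (2, (0.0, 0.010, 0.025), (0.0, 0.8, 0.4))],
    },
    "l_hip": {
        "mean": (-0.06, -0.020, 0.0),
        "harm": [(1, (0.015, 0.0, 0.030), (0.0, 0.0, 0.0)),
                 (2, (0.0, 0.012, 0.0), (0.0, _PI / 2, 0.0))],
    },
    "l_knee": {
        "mean": (-0.06, -0.255, 0.0),
        "harm": [(1, (0.010, 0.025, 0.100), (0.0, 2.0, 0.3)),
                 (2, (0.0, 0.012, 0.015), (0.0, 1.2, 0.5))],
    },
    "l_foot": {
        "mean": (-0.07, -0.435, 0.0),
        "harm": [(1, (0.008, 0.022, 0.180), (0.0, _PI / 2, 0.0)),
                 (2, (0.0, 0.010, 0.020), (0.0, 1.0, 0.6))],
    },
}


def _expand_table(table: dict[str, dict]) -> dict[str, dict]:
    """Derive right-side joints from the left-side entries.

    The right homologue keeps every amplitude, mirrors the lateral mean
    and advances the phase of each order-``k`` harmonic by ``k*pi`` so
    that its trajectory equals the left one shifted by half a gait
    period.
    """
    full: dict[str, dict] = {}
    for name, entry in table.items():
        full[name] = entry
        if name.startswith("l_"):
            ml, my, mf = entry["mean"]
            harm = [
                (k, amps, tuple(p + k * _PI for p in phases))
                for k, amps, phases in entry["harm"]
            ]
            full["r_" + name[2:]] = {"mean": (-ml, my, mf), "harm": harm}
    return full


@dataclass
class WalkerParams:
    """Configuration of the parametric walker.

    ``height`` is the head-to-foot angular extent in deg (the nominal
    stimulus size); ``direction`` is the walking azimuth in deg, drawn
    from the five values used experimentally; ``speed_target`` is the
    mean per-dot speed (deg/s) the kinematic gain is calibrated to in
    profile view.  With ``translate=False`` the walker strides in place
    (treadmill style); with ``translate=True`` it also drifts along its
    forward axis at one stride length per gait cycle.
    """

    gait_period: float = 1.0
    fps: float = 30.0
    height: float = 16.0
    direction: float = 90.0
    phase0: float = 0.0
    translate: bool = False
    speed_target: float = 9.5
    dot_diameter: float = 0.5
    gait_table: dict = field(default_factory=lambda: dict(DEFAULT_GAIT_TABLE))

    def __post_init__(self) -> None:
        if self.gait_period <= 0:
            raise ValueError("gait_period must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if float(self.direction) not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction}")
        if self.speed_target <= 0:
            raise ValueError("speed_target must be > 0")
        full = _expand_table(self.gait_table)
        if set(full) != set(JOINTS):
            raise ValueError(
                "gait table inconsistent with the 13 canonical joints: "
                f"expected {sorted(JOINTS)}, derived {sorted(full)}"
            )
        self._full_table = full

    @property
    def n_frames(self) -> int:
        return int(round(self.gait_period * self.fps))


def joint_positions(params: WalkerParams, t: np.ndarray, gain: float = 1.0,
                    direction: float | None = None) -> np.ndarray:
    """Projected joint positions at times ``t``.

    Returns an array ``(len(t), 13, 2)`` of (x, y) screen coordinates in
    deg, centred on the walker.  The projection is orthographic:
    ``x = f*sin(az) + l*cos(az)`` with ``az`` the walking azimuth, so a
    profile view (+/-90 deg) shows the full sagittal swing while a
    frontal view (0 deg) shows only lateral sway.  Periodic in
    ``gait_period`` exactly (when ``translate`` is off).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    az = math.radians(params.direction if direction is None else direction)
    theta = 2.0 * _PI * t / params.gait_period + params.phase0
    out = np.empty((t.size, len(JOINTS), 2))
    for j, name in enumerate(JOINTS):
        entry = params._full_table[name]
        ml, my, mf = entry["mean"]
        l = np.full_like(theta, ml)
        y = np.full_like(theta, my)
        f = np.full_like(theta, mf)
        for k, (al, ay, af), (pl, py, pf) in entry["harm"]:
            l = l + gain * al * np.sin(k * theta + pl)
            y = y + gain * ay * np.sin(k * theta + py)
            f = f + gain * af * np.sin(k * theta + pf)
        if params.translate:
            # one stride (~4 x foot swing amplitude) per gait cycle
            f = f + 0.36 * gain * (t / params.gait_period)
        out[:, j, 0] = f * math.sin(az) + l * math.cos(az)
        out[:, j, 1] = y
    return out * params.height


def _mean_speed(params: WalkerParams, gain: float) -> float:
    """Mean per-dot frame-to-frame speed (deg/s) in profile view."""
    t = np.arange(params.n_frames) / params.fps
    pos = joint_positions(params, t, gain=gain, direction=90.0)
    v = np.linalg.norm(np.diff(pos, axis=0), axis=2) * params.fps
    return float(v.mean())


def solve_gain(params: WalkerParams, rtol: float = 1e-3) -> float:
    """Kinematic gain giving ``speed_target`` mean dot speed in profile.

    The walk-in-place speed is exactly linear in the gain, so the direct
    ratio solves the calibration; with net translation the relation is
    only monotone and the gain is refined by bisection to ``rtol``.
    """
    base = _mean_speed(params, 1.0)
    if base <= 0:
        raise ValueError("gait table produces no motion; cannot calibrate speed")
    g = params.speed_target / base
    if not params.translate:
        return g
    lo, hi = 0.0, g
    while _mean_speed(params, hi) < params.speed_target:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        s = _mean_speed(params, mid)
        if abs(s - params.speed_target) <= rtol * params.speed_target:
            return mid
        if s < params.speed_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_walker(params: WalkerParams | None = None, seed=None) -> StimulusClip:
    """Generate one full gait cycle of the point-light walker.

    The clip covers ``[0, gait_period)`` at ``fps`` so that the frame at
    ``t = gait_period`` (cyclic wrap) coincides with frame 0.  The clip
    is deterministic given ``params``; ``seed`` is accepted for interface
    uniformity with the stochastic generators.
    """
    params = params or WalkerParams()
    gain = solve_gain(params)
    t = np.arange(params.n_frames) / params.fps
    pos = joint_positions(params, t, gain=gain)
    half = params.height / 2.0
    n = len(JOINTS)
    return StimulusClip(
        task="walker",
        truth="grouped",
        fps=params.fps,
        size=params.height,
        eccentricity=0.0,
        bbox=(-half, -half, half, half),
        positions=pos,
        diameters=np.full(n, params.dot_diameter),
        provenance=np.array([FIGURE] * n, dtype=object),
        noise_count=0,
        meta={
            "direction": float(params.direction),
            "phase0": float(params.phase0),
            "gait_period": float(params.gait_period),
            "gain": float(gain),
            "translate": bool(params.translate),
        },
    )


def scramble_walker(clip: StimulusClip, seed=None) -> StimulusClip:
    """Scramble a walker clip while preserving every local trajectory.

    Each dot keeps its own frame-to-frame displacement sequence taken
    from the upside-down walker (y-negated displacements), and starts
    from a uniformly random position inside the figure bounding box.
    Dot count, diameters, duration and the per-dot speed profile are
    unchanged; only the spatial arrangement (and vertical motion sign)
    differs, so no body percept can form.
    """
    if clip.task != "walker":
        raise ValueError(f"scramble_walker requires a walker clip, got task={clip.task!r}")
    if clip.truth != "grouped":
        raise ValueError("scramble_walker requires a grouped (unscrambled) walker clip")
    rng = np.random.default_rng(seed)
    disp = clip.displacements().copy()
    disp[:, :, 1] *= -1.0
    x0, y0, x1, y1 = clip.bbox
    starts = np.column_stack([
        rng.uniform(x0, x1, clip.n_dots),
        rng.uniform(y0, y1, clip.n_dots),
    ])
    pos = np.concatenate([starts[None, :, :], starts[None, :, :] + np.cumsum(disp, axis=0)])
    out = clip.copy()
    out.truth = "scrambled"
    out.positions = pos
    out.meta = dict(clip.meta, scrambled_from="grouped")
    return out
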