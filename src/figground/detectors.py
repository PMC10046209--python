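"""Mechanistic grouped/scrambled detectors.

The human observers of the study judged whether a dot field contained a
column-grouped object, a coherently moving group, or a point-light
walker.  These detectors close the same loop from dot coordinates to a
binary response with deliberately simple, deterministic machinery:

* :func:`column_score` -- proximity grouping.  A stimulus-sized window
  slides over the noise field; inside each window the 12 dots best
  explained by 3 or 4 fitted column abscissae (1-D k-means on x) are
  selected, and the summed horizontal residual is compared with the
  expectation for 12 uniformly placed dots.
* :func:`coherence_score` -- common fate.  Per-dot motion directions are
  taken from the first-to-last displacement; the score is the largest
  direction-coherent cluster among the dots of the best window, out
  of 12.
* :func:`walker_score` -- template matching in the spirit of global
  body-form analysis: the minimum over a bank of walker templates
  (5 azimuths x gait-phase shifts x spatial offsets) of the mean summed
  nearest-neighbour distance from template joints to clip dots,
  normalized by template height.  Lower is more walker-like.

A detector thresholds its score at a criterion calibrated on noise-free
clips to equalize hit and correct-rejection rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .clip import StimulusClip
from .grouping import DEFAULT_STATIC_CRITERION
from .layout import Layout
from .noise import noise_field_bbox
from .pipeline import StimulusConfig, make_trial_clip
from .walker import DIRECTIONS, WalkerParams, generate_walker, solve_gain, joint_positions


@dataclass
class DetectorParams:
    """Tunables of the mechanistic detectors.

    ``window`` defaults to the clip's nominal stimulus size;
    ``tolerance`` (deg) is the direction-coherence half-width of the
    dynamic detector; the walker template bank is controlled by the
    phase/offset grid densities.
    """

    window: float | None = None
    tolerance: float = 15.0
    grid_fraction: float = 0.25  # window-centre grid step, as a fraction of the window
    frame_stride: int = 3
    phase_stride: int = 2
    offset_grid: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance < 180.0:
            raise ValueError("tolerance must be in (0, 180) degrees")


def _window_centers(clip: StimulusClip, window: float, step: float) -> np.ndarray:
    """Fixed grid of window centres covering the noise field."""
    x0, y0, x1, y1 = noise_field_bbox(clip, clip.meta.get("noise_area_factor", 1.5))
    cx = np.arange(x0 + window / 2.0, x1 - window / 2.0 + 1e-9, step)
    cy = np.arange(y0 + window / 2.0, y1 - window / 2.0 + 1e-9, step)
    c = clip.center
    if cx.size == 0:
        cx = np.array([c[0]])
    if cy.size == 0:
        cy = np.array([c[1]])
    gx, gy = np.meshgrid(cx, cy)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    # the stimulus centre is always a candidate window position
    return np.vstack([grid, c])


def _kmeans_1d(x: np.ndarray, k: int, iters: int = 25) -> np.ndarray:
    """Deterministic 1-D k-means, initialized at the data quantiles."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(iters):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = x[assign == j]
            if sel.size:
                new[j] = sel.mean()
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def column_score(clip: StimulusClip, params: DetectorParams | None = None) -> float:
    """Column-alignment score in [0, 1]; deterministic given the clip.

    For each window position and for k in {3, 4} columns, the 12 dots
    with the smallest horizontal distance to the fitted column abscissae
    are selected; the score is 1 minus the best summed residual
    normalized by the expected residual of 12 uniform dots
    (``12 * window / (4k)``).
    """
    params = params or DetectorParams()
    pos = clip.positions[0]
    if pos.shape[0] < 12:
        raise ValueError("column score undefined: fewer than 12 dots in the field")
    window = params.window if params.window is not None else clip.size
    centers = _window_centers(clip, window, params.grid_fraction * window)
    best = 0.0
    half = window / 2.0
    for c in centers:
        inside = (np.abs(pos[:, 0] - c[0]) <= half) & (np.abs(pos[:, 1] - c[1]) <= half)
        x = pos[inside, 0]
        if x.size < 12:
            continue
        for k in (3, 4):
            abscissae = _kmeans_1d(x, k)
            resid = np.abs(x[:, None] - abscissae[None, :]).min(axis=1)
            total = np.sort(resid)[:12].sum()
            expected = 12.0 * window / (4.0 * k)
            score = 1.0 - total / expected
            best = max(best, score)
    return float(min(1.0, max(0.0, best)))


def coherence_score(clip: StimulusClip, params: DetectorParams | None = None) -> float:
    """Common-fate score in [0, 1] for dynamic clips.

    Directions are taken from each dot's net (first-to-last)
    displacement; the score is the size of the largest cluster of
    directions within ``tolerance`` among the dots of the best window,
    divided by 12 and capped at 1.
    """
    params = params or DetectorParams()
    if clip.task == "static":
        raise ValueError("coherence score requires a moving (dynamic) clip")
    if clip.n_frames < 2:
        raise ValueError("coherence score requires at least two frames")
    pos = clip.positions[0]
    net = clip.positions[-1] - clip.positions[0]
    angles = np.degrees(np.arctan2(net[:, 1], net[:, 0]))
    window = params.window if params.window is not None else clip.size
    centers = _window_centers(clip, window, params.grid_fraction * window)
    half = window / 2.0
    best = 0
    for c in centers:
        inside = (np.abs(pos[:, 0] - c[0]) <= half) & (np.abs(pos[:, 1] - c[1]) <= half)
        a = angles[inside]
        if a.size == 0:
            continue
        diff = np.abs((a[:, None] - a[None, :] + 180.0) % 360.0 - 180.0)
        cluster = int((diff <= params.tolerance).sum(axis=1).max())
        best = max(best, cluster)
    return float(min(1.0, best / 12.0))


def build_template_bank(walker_params: WalkerParams | None = None) -> np.ndarray:
    """Walker templates over the five azimuths, shape (5, F, 13, 2).

    Templates are generated at the reference configuration with the
    calibrated kinematic gain and centred on the origin.
    """
    params = walker_params or WalkerParams()
    gain = solve_gain(params)
    t = np.arange(params.n_frames) / params.fps
    bank = np.stack([
        joint_positions(params, t, gain=gain, direction=d) for d in DIRECTIONS
    ])
    return bank


def walker_score(clip: StimulusClip, params: DetectorParams | None = None,
                 template_bank: np.ndarray | None = None,
                 walker_params: WalkerParams | None = None) -> float:
    """Body-form template score (lower = more walker-like); >= 0.

    Minimum over the template bank (5 azimuths x gait-phase shifts x a
    spatial offset grid) of the mean over sampled frames of the summed
    nearest-neighbour distance from the 13 template joints to the clip
    dots, normalized by the template height.
    """
    params = params or DetectorParams()
    if clip.task != "walker":
        raise ValueError("walker score requires a walker-task clip")
    if template_bank is None:
        template_bank = build_template_bank(walker_params)
    if template_bank.size == 0:
        raise ValueError("empty template bank")
    n_dirs, n_tf, n_joints, _ = template_bank.shape

    # scale reference templates to the clip's size and centre
    wp = walker_params or WalkerParams()
    scale = clip.size / wp.height
    bank = template_bank * scale
    height = wp.height * scale
    center = clip.center

    shifts = np.arange(0, n_tf, params.phase_stride)
    off = (np.arange(params.offset_grid) - (params.offset_grid - 1) / 2.0)
    off = off * (clip.size * 0.125)
    ox, oy = np.meshgrid(off, off)
    offsets = np.column_stack([ox.ravel(), oy.ravel()]) + center  # (n_off, 2)

    frames = np.arange(0, clip.n_frames, params.frame_stride)
    n_shift, n_off = shifts.size, offsets.shape[0]
    total = np.zeros((n_dirs, n_shift, n_off))
    for f in frames:
        tree = cKDTree(clip.positions[f])
        t_idx = (f + shifts) % n_tf
        # (n_dirs, n_shift, n_joints, 2) -> add offsets -> flat query
        joints = bank[:, t_idx, :, :]
        pts = joints[:, :, None, :, :] + offsets[None, None, :, None, :]
        d, _ = tree.query(pts.reshape(-1, 2))
        total += d.reshape(n_dirs, n_shift, n_off, n_joints).sum(axis=3)
    mean_frame = total / frames.size
    return float(mean_frame.min() / height)


@dataclass
class Detector:
    """A calibrated score-thresholding responder for one task."""

    task: str
    params: DetectorParams
    criterion: float | None = None
    template_bank: np.ndarray | None = None
    walker_params: WalkerParams | None = None

    def score(self, clip: StimulusClip) -> float:
        if self.task == "static":
            return column_score(clip, self.params)
        if self.task == "dynamic":
            return coherence_score(clip, self.params)
        if self.task == "walker":
            return walker_score(clip, self.params, self.template_bank, self.walker_params)
        raise ValueError(f"unknown task {self.task!r}")

    @property
    def grouped_is_low(self) -> bool:
        """Polarity: the walker score decreases for grouped stimuli."""
        return self.task == "walker"

    def classify(self, clip: StimulusClip) -> str:
        if self.criterion is None:
            raise RuntimeError("detector is not calibrated: criterion is unset")
        s = self.score(clip)
        grouped = s < self.criterion if self.grouped_is_low else s > self.criterion
        return "grouped" if grouped else "scrambled"


def mechanistic_respond(detector: Detector, clip: StimulusClip) -> str:
    """Threshold the task-appropriate score at the calibrated criterion."""
    return detector.classify(clip)


def _equal_error_criterion(grouped: np.ndarray, scrambled: np.ndarray,
                           grouped_is_low: bool) -> float:
    """Criterion equalizing hit and correct-rejection rates.

    When the two score distributions separate cleanly the midpoint of
    the gap is used; otherwise the candidate cut with the smallest
    |hit - correct rejection| difference (ties: highest accuracy) wins.
    """
    g, s = np.sort(grouped), np.sort(scrambled)
    lo_hi = (g.max(), s.min()) if grouped_is_low else (s.max(), g.min())
    if lo_hi[0] < lo_hi[1]:
        return float((lo_hi[0] + lo_hi[1]) / 2.0)
    both = np.unique(np.concatenate([g, s]))
    cuts = (both[:-1] + both[1:]) / 2.0
    best_c, best_key = float(cuts[0]), (np.inf, -np.inf)
    for c in cuts:
        if grouped_is_low:
            hit = np.mean(g < c)
            cr = np.mean(s >= c)
        else:
            hit = np.mean(g > c)
            cr = np.mean(s <= c)
        key = (abs(hit - cr), -(hit + cr))
        if key < best_key:
            best_key, best_c = key, float(c)
    return best_c


def calibrate_detector(task: str, layout: Layout,
                       params: DetectorParams | None = None,
                       config: StimulusConfig | None = None,
                       n_per_class: int = 200, seed=None) -> Detector:
    """Calibrate a detector's criterion on noise-free clips.

    Generates ``n_per_class`` grouped and scrambled clips at ``layout``
    without noise, scores them, and sets the criterion at the
    equal-error point of the two score distributions.
    """
    params = params or DetectorParams()
    config = config or StimulusConfig()
    rng = np.random.default_rng(seed)
    det = Detector(task=task, params=params,
                   template_bank=build_template_bank(config.walker) if task == "walker" else None,
                   walker_params=config.walker if task == "walker" else None)
    scores = {}
    for truth in ("grouped", "scrambled"):
        vals = []
        for _ in range(n_per_class):
            clip = make_trial_clip(task, truth, 0, layout, rng, config)
            vals.append(det.score(clip))
        scores[truth] = np.asarray(vals)
    det.criterion = _equal_error_criterion(scores["grouped"], scores["scrambled"],
                                           det.grouped_is_low)
    if task == "static":
        # never let the criterion drop below the generator's rejection rule
        det.criterion = max(det.criterion, DEFAULT_STATIC_CRITERION)
    return det
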