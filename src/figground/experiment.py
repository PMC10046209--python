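"""Full experimental design and threshold aggregation.

The design crosses the three grouping tasks with eccentricities
{0, 15, 30} deg and the admissible sizes at each eccentricity, with
three staircase repeats per cell.  Observers are either parametric
psychometric responders (queried directly at each noise level) or
mechanistic detectors that judge a freshly synthesized clip on every
trial.  Aggregation mirrors the study: the three repeats of a cell are
combined (mean by default), and a task x eccentricity value per
observer is the best (largest) combined threshold over the sizes shown
at that eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import as_seed_sequence
from .detectors import Detector, mechanistic_respond
from .layout import Layout, SIZE_TABLE
from .observers import BEST_SIZES, Cohort, make_respond_fn
from .pipeline import StimulusConfig, make_trial_clip
from .staircase import StaircaseConfig, run_staircase


@dataclass(frozen=True)
class Condition:
    """One cell of the design grid."""

    task: str
    eccentricity: float
    size: float
    repeats: int = 3

    def __post_init__(self) -> None:
        sizes = SIZE_TABLE.get(float(self.eccentricity))
        if sizes is None or float(self.size) not in sizes:
            raise ValueError(
                f"(eccentricity={self.eccentricity}, size={self.size}) is not an "
                "admissible design cell"
            )
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def layout(self) -> Layout:
        return Layout(eccentricity=self.eccentricity, size=self.size)


def full_design(tasks=("static", "dynamic", "walker"), repeats: int = 3) -> list[Condition]:
    """Every task x eccentricity x admissible size cell."""
    return [
        Condition(task, ecc, size, repeats)
        for task in tasks
        for ecc, sizes in sorted(SIZE_TABLE.items())
        for size in sizes
    ]


def best_size_design(tasks=("static", "dynamic", "walker"), repeats: int = 3) -> list[Condition]:
    """One size per task x eccentricity: the group-level best size."""
    return [
        Condition(task, ecc, BEST_SIZES[(task, ecc)], repeats)
        for task in tasks
        for ecc in sorted(SIZE_TABLE)
    ]


@dataclass
class PeripheralJitter:
    """Positional jitter growing with eccentricity, for mechanistic runs.

    A demonstration device, not a claim about human vision: mechanistic
    detectors see coordinates perfectly, so without an explicit
    degradation their thresholds would not decline in the periphery.
    Per-frame, per-dot isotropic Gaussian jitter with
    ``sd = coeff * eccentricity`` (deg) emulates peripheral positional
    uncertainty.
    """

    coeff: float = 0.05

    def apply(self, clip, rng: np.random.Generator):
        sd = self.coeff * clip.eccentricity
        if sd <= 0:
            return clip
        out = clip.copy()
        out.positions = clip.positions + rng.normal(0.0, sd, clip.positions.shape)
        return out


def mechanistic_respond_fn(detector: Detector, condition: Condition,
                           config: StimulusConfig | None = None,
                           jitter: PeripheralJitter | None = None):
    """Responder that synthesizes and judges a fresh clip per trial."""
    config = config or StimulusConfig()
    jitter = jitter if jitter is not None else PeripheralJitter()
    layout = condition.layout

    def fn(level: int, truth: str, rng: np.random.Generator) -> str:
        clip = make_trial_clip(condition.task, truth, level, layout, rng, config)
        clip = jitter.apply(clip, rng)
        return mechanistic_respond(detector, clip)

    return fn


def run_condition(respond_fn, condition: Condition,
                  config: StaircaseConfig | None = None,
                  seed=None) -> list[float | None]:
    """Run the condition's staircase repeats; ``None`` marks a failed run."""
    config = config or StaircaseConfig()
    seeds = as_seed_sequence(seed).spawn(condition.repeats)
    out: list[float | None] = []
    for s in seeds:
        result = run_staircase(respond_fn, config, seed=s)
        out.append(result.threshold if result.terminated_normally else None)
    return out


def run_design(cohort: Cohort, design: list[Condition] | None = None,
               staircase_config: StaircaseConfig | None = None,
               seed=None) -> pd.DataFrame:
    """Threshold table for a parametric-observer cohort.

    Returns one row per observer x condition x repeat with columns
    ``observer_id, task, eccentricity, size, repeat, threshold, ok``.
    Per-cell seeds are derived reproducibly from the master seed.
    """
    design = design or best_size_design()
    staircase_config = staircase_config or StaircaseConfig()
    root = as_seed_sequence(seed)
    rows = []
    observers = list(cohort.thresholds.index)
    cell_seeds = root.spawn(len(observers) * len(design))
    i = 0
    for obs_id in observers:
        for cond in design:
            observer = cohort.observer(obs_id, (cond.task, cond.eccentricity))
            thresholds = run_condition(make_respond_fn(observer), cond,
                                       staircase_config, seed=cell_seeds[i])
            i += 1
            for rep, th in enumerate(thresholds):
                rows.append({
                    "observer_id": obs_id,
                    "task": cond.task,
                    "eccentricity": cond.eccentricity,
                    "size": cond.size,
                    "repeat": rep,
                    "threshold": np.nan if th is None else th,
                    "ok": th is not None,
                })
    return pd.DataFrame(rows)


def run_design_mechanistic(detectors: dict[str, Detector],
                           design: list[Condition] | None = None,
                           n_observers: int = 1,
                           stimulus_config: StimulusConfig | None = None,
                           staircase_config: StaircaseConfig | None = None,
                           jitter: PeripheralJitter | None = None,
                           seed=None) -> pd.DataFrame:
    """Threshold table for mechanistic detector observers.

    Each "observer" is an independently seeded replication of the same
    calibrated detectors; every trial synthesizes a fresh clip.
    """
    design = design or best_size_design()
    staircase_config = staircase_config or StaircaseConfig()
    root = as_seed_sequence(seed)
    rows = []
    cell_seeds = root.spawn(n_observers * len(design))
    i = 0
    for obs_id in range(n_observers):
        for cond in design:
            fn = mechanistic_respond_fn(detectors[cond.task], cond, stimulus_config, jitter)
            thresholds = run_condition(fn, cond, staircase_config, seed=cell_seeds[i])
            i += 1
            for rep, th in enumerate(thresholds):
                rows.append({
                    "observer_id": obs_id,
                    "task": cond.task,
                    "eccentricity": cond.eccentricity,
                    "size": cond.size,
                    "repeat": rep,
                    "threshold": np.nan if th is None else th,
                    "ok": th is not None,
                })
    return pd.DataFrame(rows)


def best_size_aggregate(table: pd.DataFrame, combine: str = "mean") -> pd.DataFrame:
    """Best-performance value per observer x task x eccentricity.

    The repeats of each observer x condition x size cell are combined
    (``mean`` by default, ``median`` available), then the maximum over
    sizes -- the size with the highest tolerable noise -- is taken.
    Cells whose staircases all failed are dropped with a warning flag
    left to the caller (NaN rows are excluded pairwise, never imputed).
    """
    if combine not in ("mean", "median"):
        raise ValueError("combine must be 'mean' or 'median'")
    valid = table.dropna(subset=["threshold"])
    per_size = (
        valid.groupby(["observer_id", "task", "eccentricity", "size"])["threshold"]
        .agg(combine)
        .reset_index()
    )
    agg = (
        per_size.groupby(["observer_id", "task", "eccentricity"])["threshold"]
        .max()
        .reset_index(name="value")
    )
    return agg


def summarize(agg: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Group mean, SD, SE and n per task x eccentricity."""
    if agg.empty:
        raise ValueError("cannot summarize an empty table")
    g = agg.groupby(["task", "eccentricity"])[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out
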