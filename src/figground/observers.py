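"""Synthetic psychometric observers.

Nine human participants are stood in for by parametric observers whose
probability of a *correct* grouped/scrambled judgement at noise level
``n`` follows a logistic psychometric function with guess floor and
lapse rate::

    P(correct | n) = gamma + (1 - gamma - lam) * logistic((T - n) / beta)

``T`` is the threshold location in noise dots, ``beta`` the slope, and
``gamma = 0.5`` the guessing floor of the single-presentation yes/no
task.  A cohort generator draws per-condition ``T`` values from normal
distributions matched to published group means and standard deviations,
with a shared observer-level factor inducing the within-observer
correlation across conditions that paired comparisons rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

Condition = tuple[str, float]  # (task, eccentricity)

#: Group mean and SD of the best-size threshold (noise dots) per
#: task x eccentricity, for a nine-observer cohort.
DEFAULT_GROUP_STATS: dict[Condition, tuple[float, float]] = {
    ("walker", 0.0): (94.0, 37.0),
    ("walker", 15.0): (24.0, 12.0),
    ("walker", 30.0): (13.0, 9.0),
    ("dynamic", 0.0): (50.0, 17.0),
    ("dynamic", 15.0): (18.0, 7.0),
    ("dynamic", 30.0): (12.0, 3.0),
    ("static", 0.0): (39.0, 10.0),
    ("static", 15.0): (13.0, 6.0),
    ("static", 30.0): (12.0, 4.0),
}

#: Stimulus size (deg) yielding the best group performance per condition.
BEST_SIZES: dict[Condition, float] = {
    ("walker", 0.0): 16.0,
    ("walker", 15.0): 16.0,
    ("walker", 30.0): 16.0,
    ("dynamic", 0.0): 4.0,
    ("dynamic", 15.0): 16.0,
    ("dynamic", 30.0): 16.0,
    ("static", 0.0): 4.0,
    ("static", 15.0): 20.0,
    ("static", 30.0): 16.0,
}


@dataclass(frozen=True)
class PsychometricObserver:
    """Logistic yes/no observer in noise-dot units."""

    T: float
    beta: float
    gamma: float = 0.5
    lam: float = 0.02

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not (0.0 <= self.gamma < 1.0 - self.lam <= 1.0):
            raise ValueError("require 0 <= gamma < 1 - lam <= 1")

    def p_correct(self, noise_count) -> np.ndarray | float:
        n = np.asarray(noise_count, dtype=float)
        p = self.gamma + (1.0 - self.gamma - self.lam) * expit((self.T - n) / self.beta)
        return float(p) if p.ndim == 0 else p


def respond(observer: PsychometricObserver, noise_count: int, truth: str,
            rng: np.random.Generator | int | None = None) -> str:
    """One trial: return the correct label with probability ``p_correct``."""
    if noise_count < 0:
        raise ValueError("noise_count must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    correct = rng.random() < observer.p_correct(noise_count)
    if correct:
        return truth
    return "scrambled" if truth == "grouped" else "grouped"


def make_respond_fn(observer: PsychometricObserver):
    """Adapter to the staircase's ``respond_fn(level, truth, rng)`` contract."""

    def fn(level: int, truth: str, rng: np.random.Generator) -> str:
        return respond(observer, level, truth, rng)

    return fn


@dataclass
class CohortSpec:
    """Population the observer cohort is drawn from.

    ``conditions`` maps (task, eccentricity) to the group (mean, SD) of
    the threshold location ``T``; ``rho`` is the within-observer
    correlation across conditions, imposed through a shared standard
    normal observer factor.  ``T`` draws are truncated below at 1 noise
    dot.
    """

    conditions: dict[Condition, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_STATS)
    )
    n_observers: int = 9
    rho: float = 0.7
    beta: float = 4.0
    gamma: float = 0.5
    lam: float = 0.02

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        for cond, (mean, sd) in self.conditions.items():
            if sd < 0:
                raise ValueError(f"SD must be >= 0 for condition {cond}")


@dataclass
class Cohort:
    """A sampled cohort: per-observer, per-condition threshold locations."""

    thresholds: pd.DataFrame  # index: observer id; columns: conditions
    spec: CohortSpec

    def observer(self, observer_id: int, condition: Condition) -> PsychometricObserver:
        t = float(self.thresholds[condition].loc[observer_id])
        return PsychometricObserver(T=t, beta=self.spec.beta,
                                    gamma=self.spec.gamma, lam=self.spec.lam)


def sample_cohort(spec: CohortSpec | None = None, seed=None) -> Cohort:
    """Draw a cohort of correlated observers from the spec.

    ``T_ic = mean_c + sd_c * (sqrt(rho) * Z_i + sqrt(1 - rho) * e_ic)``
    with ``Z_i`` a shared observer factor and ``e_ic`` independent
    standard normals, truncated below at 1.  With ``sd = 0`` every
    observer takes the condition mean exactly.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    conds = list(spec.conditions)
    z = rng.standard_normal(spec.n_observers)
    data = np.empty((spec.n_observers, len(conds)))
    for j, cond in enumerate(conds):
        mean, sd = spec.conditions[cond]
        e = rng.standard_normal(spec.n_observers)
        t = mean + sd * (np.sqrt(spec.rho) * z + np.sqrt(1.0 - spec.rho) * e)
        data[:, j] = np.maximum(t, 1.0)
    frame = pd.DataFrame(data, columns=pd.Index(conds, tupleize_cols=False))
    frame.index.name = "observer_id"
    return Cohort(thresholds=frame, spec=spec)
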