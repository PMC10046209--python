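"""Qualitative-replication harness.

Simulates complete experiments -- cohort draw, staircases over the
design, best-size aggregation, statistics -- and checks whether each
simulated experiment reproduces the study's significance pattern at the
Bonferroni-adjusted alpha:

* the walker task tolerates significantly more noise than the static
  and the dynamic grouping task in the central field;
* static vs dynamic is not significant;
* within every task, the central threshold significantly exceeds the
  thresholds at 15 and 30 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeding import as_seed_sequence
from .experiment import best_size_aggregate, best_size_design, run_design
from .observers import CohortSpec, sample_cohort
from .staircase import StaircaseConfig
from .stats import MultipleComparisonPolicy, paired_t

PATTERN_CHECKS = (
    "walker_gt_static",
    "walker_gt_dynamic",
    "static_dynamic_ns",
    "central_gt_periphery",
)


def _pair(agg: pd.DataFrame, a, b) -> tuple[np.ndarray, np.ndarray]:
    x = agg[(agg["task"] == a[0]) & (agg["eccentricity"] == a[1])]
    y = agg[(agg["task"] == b[0]) & (agg["eccentricity"] == b[1])]
    m = x.merge(y, on="observer_id", suffixes=("_a", "_b"))
    return m["value_a"].to_numpy(), m["value_b"].to_numpy()


def pattern_checks(agg: pd.DataFrame,
                   policy: MultipleComparisonPolicy | None = None) -> dict[str, bool]:
    """Evaluate the significance pattern on one aggregated table."""
    policy = policy or MultipleComparisonPolicy()
    alpha = policy.adjusted_alpha

    def sig_greater(a, b) -> bool:
        x, y = _pair(agg, a, b)
        r = paired_t(x, y)
        return bool(r.p < alpha and r.mean_diff > 0)

    out = {
        "walker_gt_static": sig_greater(("walker", 0.0), ("static", 0.0)),
        "walker_gt_dynamic": sig_greater(("walker", 0.0), ("dynamic", 0.0)),
    }
    x, y = _pair(agg, ("static", 0.0), ("dynamic", 0.0))
    out["static_dynamic_ns"] = bool(paired_t(x, y).p >= alpha)
    out["central_gt_periphery"] = all(
        sig_greater((task, 0.0), (task, ecc))
        for task in ("static", "dynamic", "walker")
        for ecc in (15.0, 30.0)
    )
    out["all"] = all(out[k] for k in PATTERN_CHECKS)
    return out


@dataclass
class ReplicationOutcome:
    rate: float
    checks: pd.DataFrame  # one row per simulated experiment

    @property
    def per_check_rates(self) -> pd.Series:
        return self.checks[list(PATTERN_CHECKS)].mean()


def simulate_experiment(spec: CohortSpec | None = None,
                        design=None,
                        staircase_config: StaircaseConfig | None = None,
                        seed=None) -> pd.DataFrame:
    """One full simulated experiment, returning the aggregated table."""
    spec = spec or CohortSpec()
    design = design or best_size_design()
    ss = as_seed_sequence(seed)
    s_cohort, s_design = ss.spawn(2)
    cohort = sample_cohort(spec, seed=s_cohort)
    table = run_design(cohort, design, staircase_config, seed=s_design)
    return best_size_aggregate(table)


def replication_rate(n_experiments: int = 100,
                     spec: CohortSpec | None = None,
                     design=None,
                     staircase_config: StaircaseConfig | None = None,
                     policy: MultipleComparisonPolicy | None = None,
                     seed=None) -> ReplicationOutcome:
    """Fraction of simulated experiments reproducing the full pattern."""
    seeds = as_seed_sequence(seed).spawn(n_experiments)
    rows = []
    for s in seeds:
        agg = simulate_experiment(spec, design, staircase_config, seed=s)
        rows.append(pattern_checks(agg, policy))
    checks = pd.DataFrame(rows)
    return ReplicationOutcome(rate=float(checks["all"].mean()), checks=checks)
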