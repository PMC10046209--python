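"""YAML/JSON configuration round-trip for the pipeline defaults."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .observers import CohortSpec
from .staircase import StaircaseConfig


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "conditions": [
            {"task": task, "eccentricity": ecc, "mean": mean, "sd": sd}
            for (task, ecc), (mean, sd) in spec.conditions.items()
        ],
        "n_observers": spec.n_observers,
        "rho": spec.rho,
        "beta": spec.beta,
        "gamma": spec.gamma,
        "lam": spec.lam,
    }


def cohort_spec_from_dict(doc: dict) -> CohortSpec:
    conditions = {
        (c["task"], float(c["eccentricity"])): (float(c["mean"]), float(c["sd"]))
        for c in doc["conditions"]
    }
    return CohortSpec(
        conditions=conditions,
        n_observers=int(doc.get("n_observers", 9)),
        rho=float(doc.get("rho", 0.7)),
        beta=float(doc.get("beta", 4.0)),
        gamma=float(doc.get("gamma", 0.5)),
        lam=float(doc.get("lam", 0.02)),
    )


def staircase_config_to_dict(cfg: StaircaseConfig) -> dict:
    return {
        "block_size": cfg.block_size,
        "start_level": cfg.start_level,
        "first_jump": cfg.first_jump,
        "step_schedule": [list(pair) for pair in cfg.step_schedule],
        "final_step": cfg.final_step,
        "final_reversals": cfg.final_reversals,
        "floor": cfg.floor,
        "max_blocks": cfg.max_blocks,
        "p_grouped": cfg.p_grouped,
    }


def staircase_config_from_dict(doc: dict) -> StaircaseConfig:
    defaults = StaircaseConfig()
    schedule = doc.get("step_schedule")
    return StaircaseConfig(
        block_size=int(doc.get("block_size", defaults.block_size)),
        start_level=int(doc.get("start_level", defaults.start_level)),
        first_jump=int(doc.get("first_jump", defaults.first_jump)),
        step_schedule=(
            tuple(tuple(int(v) for v in pair) for pair in schedule)
            if schedule is not None else defaults.step_schedule
        ),
        final_step=int(doc.get("final_step", defaults.final_step)),
        final_reversals=int(doc.get("final_reversals", defaults.final_reversals)),
        floor=int(doc.get("floor", defaults.floor)),
        max_blocks=int(doc.get("max_blocks", defaults.max_blocks)),
        p_grouped=float(doc.get("p_grouped", defaults.p_grouped)),
    )


def save_config(doc: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc))


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
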