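"""Block-up-and-down (BUDTIF) threshold procedure.

The stimulus level is the number of noise dots.  Each level is presented
for a block of four trials; only if all four responses are correct does
the level move up (harder), otherwise it moves down.  The level starts
at 0 and first jumps to 20; the step size is reduced from 20 to 10 after
two reversals of direction and from 10 to 5 after two further reversals.
The run ends once a configured number of reversals has occurred at step
size 5, and the threshold is the median of the levels at which those
step-5 reversals happened.

Because a block moves up only with probability ``p(correct)**4``, the
procedure converges on the level where ``p(correct) = 0.5**(1/4)``,
i.e. the ~84.1 %-correct point of the psychometric function.

A reversal is recorded at the level where the direction changes and is
tagged with the step size used by the move that *reached* that level;
reversal quotas are counted strictly within each step phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

Response = str  # "grouped" | "scrambled"
RespondFn = Callable[[int, str, np.random.Generator], Response]


@dataclass(frozen=True)
class StaircaseConfig:
    """BUDTIF schedule parameters.

    ``step_schedule`` holds the preparatory ``(step, reversals_to_advance)``
    phases; ``final_step``/``final_reversals`` describe the measuring
    phase whose reversal levels define the threshold.  An even
    ``final_reversals`` is recommended so the median falls between the
    two oscillation levels.
    """

    block_size: int = 4
    start_level: int = 0
    first_jump: int = 20
    step_schedule: tuple[tuple[int, int], ...] = ((20, 2), (10, 2))
    final_step: int = 5
    final_reversals: int = 6
    floor: int = 0
    max_blocks: int = 200
    p_grouped: float = 0.5  # probability a trial shows the grouped stimulus

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        steps = [s for s, _ in self.step_schedule] + [self.final_step]
        if any(s <= 0 for s in steps) or any(a <= b for a, b in zip(steps, steps[1:])):
            raise ValueError("step sizes must be positive and strictly decreasing")
        if any(q < 1 for _, q in self.step_schedule):
            raise ValueError("phase reversal quotas must be >= 1")
        if self.final_reversals < 2:
            raise ValueError("final_reversals must be >= 2")
        if not 0.0 < self.p_grouped < 1.0:
            raise ValueError("p_grouped must be in (0, 1)")

    @property
    def steps(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.step_schedule) + (self.final_step,)


@dataclass(frozen=True)
class TrialRecord:
    block_index: int
    trial_index: int
    level: int
    truth: str
    response: str
    correct: bool


@dataclass(frozen=True)
class Reversal:
    level: int
    step_in_effect: int


@dataclass(frozen=True)
class StaircaseState:
    """Pure state of the staircase between blocks."""

    level: int
    phase: int = 0  # index into (step_schedule..., final phase)
    reversals_in_phase: int = 0
    prev_dir: int = 0  # +1 up, -1 down, 0 before the first block
    arrival_step: int | None = None  # step used by the move that reached `level`
    n_moves: int = 0
    done: bool = False


def initial_state(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(level=config.start_level)


def _current_step(state: StaircaseState, config: StaircaseConfig) -> int:
    if state.phase < len(config.step_schedule):
        return config.step_schedule[state.phase][0]
    return config.final_step


def next_state(state: StaircaseState, all_correct: bool,
               config: StaircaseConfig) -> tuple[StaircaseState, Reversal | None]:
    """Advance the staircase by one completed block.

    Deterministic and total on valid states: moves up on an all-correct
    block and down otherwise, records a reversal when the direction
    changes after the first move, advances the step phase when the
    phase's reversal quota is met, and clamps the level at the floor.
    """
    if state.done:
        raise ValueError("staircase already terminated")
    direction = 1 if all_correct else -1

    reversal = None
    phase, in_phase, done = state.phase, state.reversals_in_phase, False
    if state.prev_dir != 0 and direction != state.prev_dir and state.n_moves > 0:
        step_tag = state.arrival_step if state.arrival_step is not None else _current_step(state, config)
        reversal = Reversal(level=state.level, step_in_effect=step_tag)
        if state.phase < len(config.step_schedule):
            if step_tag == config.step_schedule[state.phase][0]:
                in_phase += 1
                if in_phase >= config.step_schedule[state.phase][1]:
                    phase += 1
                    in_phase = 0
        else:
            if step_tag == config.final_step:
                in_phase += 1
                if in_phase >= config.final_reversals:
                    done = True

    if done:
        new = replace(state, phase=phase, reversals_in_phase=in_phase,
                      prev_dir=direction, done=True)
        return new, reversal

    # the move away from a reversal uses the (possibly advanced) step
    probe = replace(state, phase=phase)
    step = _current_step(probe, config)
    if state.n_moves == 0 and direction > 0:
        step = config.first_jump
    new_level = max(config.floor, state.level + direction * step)
    new = StaircaseState(
        level=new_level,
        phase=phase,
        reversals_in_phase=in_phase,
        prev_dir=direction,
        arrival_step=step,
        n_moves=state.n_moves + 1,
        done=False,
    )
    return new, reversal


@dataclass
class StaircaseResult:
    trials: list[TrialRecord]
    reversals: list[Reversal]
    config: StaircaseConfig
    terminated_normally: bool
    levels: list[int] = field(default_factory=list)  # level of each block

    @property
    def final_step_reversals(self) -> list[int]:
        return [r.level for r in self.reversals if r.step_in_effect == self.config.final_step]

    @property
    def threshold(self) -> float | None:
        levels = self.final_step_reversals
        if not levels:
            return None
        return float(np.median(levels))


def run_staircase(respond_fn: RespondFn, config: StaircaseConfig | None = None,
                  seed=None) -> StaircaseResult:
    """Run one BUDTIF staircase against a responder.

    ``respond_fn(level, truth, rng)`` must return ``"grouped"`` or
    ``"scrambled"``; each trial's true stimulus class is drawn Bernoulli
    (``p_grouped``).  The run stops after ``final_reversals`` reversals
    in the step-5 phase or, failing that, after ``max_blocks`` blocks
    with ``terminated_normally=False``.
    """
    config = config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    state = initial_state(config)
    trials: list[TrialRecord] = []
    reversals: list[Reversal] = []
    levels: list[int] = []

    for block in range(config.max_blocks):
        levels.append(state.level)
        all_correct = True
        for i in range(config.block_size):
            truth = "grouped" if rng.random() < config.p_grouped else "scrambled"
            response = respond_fn(state.level, truth, rng)
            correct = response == truth
            all_correct &= correct
            trials.append(TrialRecord(block, i, state.level, truth, response, correct))
        state, reversal = next_state(state, all_correct, config)
        if reversal is not None:
            reversals.append(reversal)
        if state.done:
            return StaircaseResult(trials, reversals, config, True, levels)
    return StaircaseResult(trials, reversals, config, False, levels)


def estimate_threshold(result: StaircaseResult) -> float:
    """Median of the step-5 reversal levels (midpoint for an even count)."""
    levels = result.final_step_reversals
    if not levels:
        raise ValueError("no final-step reversals: threshold is undefined")
    return float(np.median(levels))


def trial_log_frame(result: StaircaseResult):
    """Trial log as a DataFrame (block, trial, level, truth, response, correct)."""
    import pandas as pd

    return pd.DataFrame([t.__dict__ for t in result.trials])


def write_trial_log(result: StaircaseResult, path) -> None:
    """CSV trial log with the configuration echoed as comment headers."""
    from pathlib import Path

    cfg = result.config
    header = (
        f"# block_size={cfg.block_size} start_level={cfg.start_level} "
        f"first_jump={cfg.first_jump} step_schedule={cfg.step_schedule} "
        f"final_step={cfg.final_step} final_reversals={cfg.final_reversals} "
        f"floor={cfg.floor} max_blocks={cfg.max_blocks}\n"
    )
    body = trial_log_frame(result).to_csv(index=False)
    Path(path).write_text(header + body)
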