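"""Independent brute-force simulator of the block-up-and-down rules.

Written directly from the published procedure, deliberately not sharing
any code with the package implementation: each noise level is shown for
a block of four trials; if all four responses are correct the level
goes up, otherwise down; the level starts at 0 and the first increase
is to 20; after two reversals the step drops to 10, after two more to
5; a reversal is logged at the level where the direction changed,
tagged with the step used by the move that reached that level; the run
stops at the sixth reversal under step 5 and the threshold is the
median of the step-5 reversal levels.
"""

from statistics import median


def simulate_cutoff_staircase(cutoff, n_step5=6, max_blocks=200):
    """Level/reversal trace for an observer correct iff level <= cutoff.

    Returns ``(levels, reversals, threshold)`` where ``levels`` is the
    level of every block in order, ``reversals`` a list of
    ``(level, step_tag)`` pairs and ``threshold`` the median of the
    step-5 reversal levels (None when the run never finished).
    """
    phases = [(20, 2), (10, 2), (5, n_step5)]
    phase = 0
    revs_here = 0

    level = 0
    levels = []
    reversals = []
    last_dir = None      # direction of the previous block outcome
    arrived_by = None    # step used by the move that reached `level`
    moved = False

    for _ in range(max_blocks):
        levels.append(level)
        going_up = level <= cutoff  # all four trials correct iff level <= cutoff

        if moved and last_dir is not None and going_up != last_dir:
            tag = arrived_by
            reversals.append((level, tag))
            if tag == phases[phase][0]:
                revs_here += 1
                if revs_here >= phases[phase][1]:
                    if phase == len(phases) - 1:
                        threshold = median(l for l, s in reversals if s == 5)
                        return levels, reversals, threshold
                    phase += 1
                    revs_here = 0

        step = phases[phase][0]
        level = max(0, level + (step if going_up else -step))
        arrived_by = step
        last_dir = going_up
        moved = True

    return levels, reversals, None
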