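"""Measure one noise-dot threshold with the block-up-and-down staircase.

A parametric observer with threshold location T = 50 answers a yes/no
grouped-vs-scrambled question; the staircase raises the noise level
after each fully correct block of four trials and lowers it otherwise,
finishing when six reversals have occurred at step size 5.
"""

import numpy as np

import figground as fg

observer = fg.PsychometricObserver(T=50, beta=4)
result = fg.run_staircase(fg.make_respond_fn(observer), fg.StaircaseConfig(), seed=7)

print(f"blocks run: {len(result.levels)}, trials: {len(result.trials)}")
print(f"level sequence: {result.levels}")
print("reversals (level, step):",
      [(r.level, r.step_in_effect) for r in result.reversals])
print(f"threshold = median of step-5 reversal levels = {result.threshold} noise dots")

# blocks of four target the ~84.1 %-correct point of the psychometric
# function, which for this observer sits slightly below T:
p = 0.5 ** 0.25
target = observer.T - observer.beta * np.log(
    (p - observer.gamma) / (1 - observer.lam - p))
print(f"analytic convergence point for this observer: {target:.1f} noise dots")

fg.write_trial_log(result, "staircase_log.csv")
print("trial log written to staircase_log.csv")
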