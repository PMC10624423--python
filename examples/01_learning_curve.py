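"""Behavioral learning curve: binned d', sigmoid fit, learning threshold.

Simulates a go/no-go texture-discrimination subject whose sensitivity
follows a sigmoid across trials, recovers the curve from the trial table,
and assigns the naive/learning/expert sessions around the fitted threshold.
"""

import numpy as np

from trialhist import SynthConfig, behavior, synthdata

cfg = SynthConfig(n_trials=2500, n_sessions=5, learn_a=2.5, learn_b=1000,
                  learn_c=150, history_onset_learning=1500, seed=1)
table = synthdata.simulate_behavior(cfg)

curve = behavior.bin_learning_curve(table, bin_size=100)
fit = behavior.fit_sigmoid(curve)
threshold = behavior.learning_threshold(fit)
phases = behavior.assign_phases(table, threshold)

print("binned d' (100-trial bins):")
print(np.round(curve.dprime, 2))
print(f"sigmoid fit: a={fit.a:.2f} d', b={fit.b:.0f} trials, c={fit.c:.0f} trials")
print(f"learning threshold (inflection trial): {threshold:.0f}  [true b = {cfg.learn_b}]")
print(f"phases: naive={phases.naive}  learning={phases.learning}  expert={phases.expert}")

# d' rises from ~0 to the fitted amplitude a; the threshold is the trial at
# which the animal is halfway to expert performance, and the session
# containing it becomes the 'learning' day.
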