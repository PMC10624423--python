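"""History modulation and its onsets in trial time and learning time.

The history modulation index is mean(CR-Hit) - mean(Hit-Hit): the extra
activity on Hit trials that were preceded by a correct rejection.  Its
onset is the first frame (or 100-trial bin) exceeding the mean + 2 SD of a
1000-iteration trial-shuffle null.
"""

from trialhist import SynthConfig, behavior, historymod, synthdata

cfg = SynthConfig(n_trials=2500, n_sessions=5, learn_b=1000, learn_c=150,
                  history_onset_learning=1500, history_effect=0.03,
                  noise_sd=0.04, seed=2)
table = synthdata.simulate_behavior(cfg)
tensor, control, truth = synthdata.simulate_session_tensor(table, cfg)

fit = behavior.fit_sigmoid(behavior.bin_learning_curve(table))
threshold = behavior.learning_threshold(fit)
phases = behavior.assign_phases(table, threshold)

for phase, sess in phases.as_dict().items():
    if sess is None:
        continue
    res = historymod.trialtime_modulation(tensor, table, area="BC",
                                          session_id=sess, seed=0)
    onset = "none" if res.onset_time_s is None else f"{res.onset_time_s:+.2f} s"
    print(f"{phase:9s} ({sess}): BC trial-time onset {onset} "
          f"(n={res.n_a} CR-Hit / {res.n_b} Hit-Hit)")

lm = historymod.learning_modulation(tensor, table, threshold, area="BC", seed=0)
print(f"learning-time onset: trial {lm.onset_trial:.0f} "
      f"({lm.onset_trial_rel:+.0f} relative to threshold; "
      f"injected switch-on at trial {cfg.history_onset_learning})")

# Before the injected learning-time onset no band crossing is expected;
# after it the modulation exceeds the shuffle band inside the stim window
# ([-0.2, 0.2) s around texture stop), where the BC effect was injected.
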