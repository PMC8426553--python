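"""Train the multi-head attention LSTM on synthetic salient-window data.

Generates two classes of variable-length feature sequences whose only
difference is a mean shift confined to the central 20% of each class-1
sequence, trains the 4-head model, and reports held-out UAR plus how much
attention mass lands inside the (never revealed to the model) salient
window.  Runs in about a minute on one CPU.
"""

from attnspeech.study import salience_study

result = salience_study(seed=1)

print(f"train/test sizes: {result.n_train}/{result.n_test}, "
      f"{result.epochs_run} epochs")
print(f"held-out UAR: {result.test_uar:.3f}")
print(f"mean attention mass in salient window: {result.attention_mass:.3f} "
      f"(uniform baseline {result.window_fraction:.2f})")
# UAR near 1.0 shows the classifier found the class signal; attention mass
# above the 0.20 baseline shows the attention heads localized *where* the
# signal lives without being told.
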